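"""Tab-separated table IO with provenance comment headers.

All tool outputs are plain TSV: UTF-8, tab-separated, no quoting, with
'#'-prefixed comment lines carrying the tool version and a hash of the run
configuration so outputs are traceable and bit-comparable.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Mapping, Optional

import pandas as pd


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(
    frame: pd.DataFrame,
    path: str,
    config: Optional[Mapping[str, Any]] = None,
) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# tandemkit={__version__}\n")
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
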