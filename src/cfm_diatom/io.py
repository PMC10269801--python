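"""Table input/output with reproducibility headers.

Every table written by the package starts with comment lines recording
the package version, a hash of the run configuration and the seed, so
any output can be regenerated bit for bit from its header alone.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import RunConfig, metadata_header

__all__ = ["write_table", "read_table"]


def write_table(
    df: pd.DataFrame,
    path,
    config: RunConfig,
    seed: int | None = None,
    sep: str = ",",
) -> Path:
    """Write a DataFrame as CSV/TSV prefixed with the metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\n".join(metadata_header(config, seed))
    with path.open("w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep=sep, index=False)
    return path


def read_table(path, sep: str = ",") -> pd.DataFrame:
    """Read a table written by :func:`write_table`, skipping metadata."""
    return pd.read_csv(path, sep=sep, comment="#")
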