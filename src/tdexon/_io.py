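"""TSV I/O with '#'-prefixed metadata headers."""

from __future__ import annotations

import pandas as pd

from . import __version__


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a DataFrame as TSV with a commented metadata header block."""
    with open(path, "w") as fh:
        fh.write(f"# tdexon_version: {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)
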