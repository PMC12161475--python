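"""Readers and writers for the plain-text formats the pipeline touches.

Tables are tab-separated with a single ``#``-prefixed provenance line naming
the tool version and configuration hash; readers skip comment lines, so the
files remain valid input for standard tooling. Gene sets use the GMT dialect
(name, description, members). Parsing is strict: malformed lines raise with
the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__


class ParseError(ValueError):
    """Raised on malformed input files, carrying file and line context."""


def _provenance(config_hash: str | None) -> str:
    tag = f" config={config_hash}" if config_hash else ""
    return f"# crcprofiler v{__version__}{tag}\n"


def write_table(df: pd.DataFrame, path: str | Path,
                config_hash: str | None = None) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config_hash))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{what} is missing required column(s): {missing}")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered name -> member-gene-list mapping.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``. Lines with
    fewer than three fields and duplicate set names are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and >= 1 gene")
            name, desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    read_gmt.last_descriptions = descriptions  # type: ignore[attr-defined]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: str | Path,
                 config_hash: str | None = None) -> None:
    """Write a gene x sample matrix; the index (gene) becomes the first column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config_hash))
        df.to_csv(fh, sep="\t", index=True, index_label="gene",
                  float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    return df.set_index(df.columns[0])
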