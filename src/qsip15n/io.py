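"""Readers and writers for the delimited-text interchange formats.

All tables are UTF-8, comma- or tab-delimited (auto-detected from the
header line; pass ``sep`` explicitly to override sniffing).  Writers
emit a ``#`` comment line carrying the package version so outputs are
traceable.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import (
    FormatError,
    GradientFraction,
    SampleMeta,
    TaxonAbundanceMatrix,
    TubeGradient,
    ValidationError,
)

FRACTION_COLUMNS = ["tube_id", "sample_id", "fraction_id", "density", "total_copies"]
SAMPLE_COLUMNS = ["sample_id", "site", "method", "plot", "label"]


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: empty file")


def _read_table(path: str | Path, sep: str | None, index_col=None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path, sep), comment="#", index_col=index_col)


def _header_comment() -> str:
    from . import __version__

    return f"# qsip15n v{__version__}\n"


def _write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t", index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep=sep, index=index)
    path.write_text(_header_comment() + buf.getvalue(), encoding="utf-8")


def read_fraction_table(path: str | Path, sep: str | None = None) -> list[TubeGradient]:
    """Read per-tube fraction densities and qPCR totals.

    One :class:`TubeGradient` per ``tube_id``, fractions sorted by
    density ascending regardless of row order in the file.
    """
    df = _read_table(path, sep)
    missing = [c for c in FRACTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    tubes: list[TubeGradient] = []
    for tube_id, grp in df.groupby("tube_id", sort=True):
        sample_ids = grp["sample_id"].unique()
        if len(sample_ids) != 1:
            raise ValidationError(f"tube {tube_id!r}: multiple sample_ids {list(sample_ids)}")
        fracs = []
        for row in grp.itertuples():
            try:
                fracs.append(
                    GradientFraction(
                        fraction_id=str(row.fraction_id),
                        density=float(row.density),
                        total_copies=float(row.total_copies),
                    )
                )
            except ValidationError as e:
                raise ValidationError(f"{path} row {row.Index}: {e}") from e
        tubes.append(TubeGradient.from_unsorted(str(tube_id), str(sample_ids[0]), fracs))
    return tubes


def write_fraction_table(tubes: Sequence[TubeGradient], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "tube_id": t.tube_id,
            "sample_id": t.sample_id,
            "fraction_id": f.fraction_id,
            "density": f.density,
            "total_copies": f.total_copies,
        }
        for t in tubes
        for f in t.fractions
    ]
    _write_table(pd.DataFrame(rows, columns=FRACTION_COLUMNS), path, sep=sep)


def read_taxon_counts(
    path: str | Path,
    taxonomy_path: str | Path,
    tubes: Sequence[TubeGradient],
    sep: str | None = None,
) -> TaxonAbundanceMatrix:
    """Read a taxon x fraction count matrix plus its taxonomy table.

    The counts file has taxon ids in the first column and fraction ids
    as remaining column names; every fraction id must belong to exactly
    one of ``tubes``.  Filtering (all-zero rows etc.) is a later stage;
    rows are kept as read.
    """
    counts = _read_table(path, sep, index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    tax_df = _read_table(taxonomy_path, sep)
    if not {"taxon_id", "taxonomy"} <= set(tax_df.columns):
        raise FormatError(f"{taxonomy_path}: needs columns taxon_id, taxonomy")
    taxonomy = tax_df.set_index(tax_df["taxon_id"].astype(str))["taxonomy"].astype(str)
    if taxonomy.index.duplicated().any():
        dup = sorted(taxonomy.index[taxonomy.index.duplicated()].unique())
        raise ValidationError(f"{taxonomy_path}: duplicate taxon ids {dup}")

    frac_to_tube: dict[str, str] = {}
    for t in tubes:
        for fid in t.fraction_ids:
            if fid in frac_to_tube:
                raise ValidationError(f"fraction id {fid!r} appears in more than one tube")
            frac_to_tube[fid] = t.tube_id

    missing = sorted(set(counts.index) - set(taxonomy.index))
    if missing:
        raise ValidationError(f"{path}: taxa without taxonomy entries: {missing}")
    return TaxonAbundanceMatrix(
        counts=counts.astype(float),
        taxonomy=taxonomy.loc[list(counts.index)],
        fraction_to_tube=frac_to_tube,
    )


def write_taxon_counts(
    m: TaxonAbundanceMatrix, counts_path: str | Path, taxonomy_path: str | Path, sep: str = "\t"
) -> None:
    counts = m.counts.copy()
    counts.index.name = "taxon_id"
    _write_table(counts, counts_path, sep=sep, index=True)
    tax = m.taxonomy.rename("taxonomy").rename_axis("taxon_id").reset_index()
    _write_table(tax, taxonomy_path, sep=sep)


def read_sample_table(path: str | Path, sep: str | None = None) -> list[SampleMeta]:
    df = _read_table(path, sep)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            site=str(r.site),
            method=str(r.method),
            plot=int(r.plot),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def write_sample_table(metas: Sequence[SampleMeta], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {"sample_id": m.sample_id, "site": m.site, "method": m.method, "plot": m.plot, "label": m.label}
        for m in metas
    ]
    _write_table(pd.DataFrame(rows, columns=SAMPLE_COLUMNS), path, sep=sep)


def write_result_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write any result DataFrame with the standard version header."""
    _write_table(df, path, sep=sep)
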