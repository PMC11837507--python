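"""Domain types for density-gradient qSIP data and study design validation.

The experimental unit is one ultracentrifuge tube per DNA sample,
fractionated into ~25 density fractions.  Each fraction carries a
buoyant density (refractometer) and a total 16S rRNA gene copy number
(qPCR); amplicon counts per taxon are stored separately as a
:class:`TaxonAbundanceMatrix` whose columns map back to tubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SITES = ("Valley", "Ridge")
METHODS = ("field", "lab")
LABELS = ("unlabeled", "labeled")


class FormatError(ValueError):
    """A required column or structural element is missing from an input file."""


class ValidationError(ValueError):
    """Input values violate a domain invariant (named row/record in message)."""


class DesignError(ValueError):
    """The sample metadata does not form a valid paired labeling design."""


@dataclass(frozen=True)
class GradientFraction:
    """One density fraction of a tube.

    Parameters
    ----------
    fraction_id : str
        Identifier, unique within its tube (and globally in practice).
    density : float
        Buoyant density in g/mL; plausible CsCl gradient values only.
    total_copies : float
        Total 16S rRNA gene copies measured by qPCR; non-negative.
    """

    fraction_id: str
    density: float
    total_copies: float

    def __post_init__(self) -> None:
        if not (1.5 < self.density < 2.0):
            raise ValidationError(
                f"fraction {self.fraction_id!r}: density {self.density} g/mL "
                "outside the plausible CsCl range (1.5, 2.0)"
            )
        if self.total_copies < 0 or not np.isfinite(self.total_copies):
            raise ValidationError(
                f"fraction {self.fraction_id!r}: total_copies {self.total_copies} "
                "must be finite and >= 0"
            )


@dataclass(frozen=True)
class TubeGradient:
    """One ultracentrifuge tube: ordered fractions with densities and totals."""

    tube_id: str
    sample_id: str
    fractions: tuple[GradientFraction, ...]
    unusable: bool = False

    def __post_init__(self) -> None:
        if len(self.fractions) < 3 and not self.unusable:
            raise ValidationError(
                f"tube {self.tube_id!r}: needs >= 3 fractions, got {len(self.fractions)}"
            )
        ids = [f.fraction_id for f in self.fractions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"tube {self.tube_id!r}: duplicate fraction ids {dup}")
        dens = self.densities
        if np.any(np.diff(dens) <= 0):
            raise ValidationError(
                f"tube {self.tube_id!r}: densities not strictly increasing after sort"
            )

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions], dtype=float)

    @property
    def total_copies(self) -> np.ndarray:
        return np.array([f.total_copies for f in self.fractions], dtype=float)

    @property
    def fraction_ids(self) -> list[str]:
        return [f.fraction_id for f in self.fractions]

    @staticmethod
    def from_unsorted(
        tube_id: str, sample_id: str, fractions: Sequence[GradientFraction]
    ) -> "TubeGradient":
        """Build a tube sorting fractions by density ascending."""
        ordered = tuple(sorted(fractions, key=lambda f: f.density))
        return TubeGradient(tube_id, sample_id, ordered)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one DNA sample (== one tube)."""

    sample_id: str
    site: str
    method: str  # 'field' or 'lab'; unlabeled controls carry the shared value 'pre'
    plot: int
    label: str  # 'unlabeled' | 'labeled'

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"sample {self.sample_id!r}: unknown site {self.site!r}")
        if self.label not in LABELS:
            raise ValidationError(f"sample {self.sample_id!r}: unknown label {self.label!r}")
        if self.label == "labeled" and self.method not in METHODS:
            raise ValidationError(
                f"sample {self.sample_id!r}: labeled sample needs method in {METHODS}"
            )
        if not (1 <= int(self.plot) <= 7):
            raise ValidationError(f"sample {self.sample_id!r}: plot {self.plot} outside 1..7")


@dataclass(frozen=True)
class StudyDesign:
    """Validated pairing of labeled samples to their plot's unlabeled control."""

    samples: tuple[SampleMeta, ...]
    pairing: Mapping[str, str]  # labeled sample_id -> unlabeled sample_id

    @property
    def labeled(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.label == "labeled"]

    @property
    def unlabeled(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.label == "unlabeled"]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def validate_design(metas: Sequence[SampleMeta]) -> StudyDesign:
    """Pair each labeled sample with its (site, plot) unlabeled control.

    The single pre-incubation sample per plot serves as the natural
    abundance control for both the field and the lab labeled sample of
    that plot.  Order of the input is irrelevant.

    Raises
    ------
    DesignError
        If a plot has a labeled sample but no unlabeled control, more
        than one unlabeled control (ambiguous pairing), or duplicated
        (site, plot, method) labeled samples.
    """
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise DesignError(f"duplicate sample ids {dup}")

    controls: dict[tuple[str, int], list[SampleMeta]] = {}
    for m in metas:
        if m.label == "unlabeled":
            controls.setdefault((m.site, int(m.plot)), []).append(m)
    for key, ctl in controls.items():
        if len(ctl) > 1:
            raise DesignError(
                f"site {key[0]} plot {key[1]}: {len(ctl)} unlabeled samples; pairing ambiguous"
            )

    seen_labeled: set[tuple[str, int, str]] = set()
    pairing: dict[str, str] = {}
    for m in metas:
        if m.label != "labeled":
            continue
        key = (m.site, int(m.plot))
        lkey = (m.site, int(m.plot), m.method)
        if lkey in seen_labeled:
            raise DesignError(
                f"site {m.site} plot {m.plot}: more than one {m.method} labeled sample"
            )
        seen_labeled.add(lkey)
        if key not in controls:
            raise DesignError(
                f"labeled sample {m.sample_id!r} (site {m.site}, plot {m.plot}) "
                "has no same-plot unlabeled control"
            )
        pairing[m.sample_id] = controls[key][0].sample_id

    ordered = tuple(sorted(metas, key=lambda s: (s.site, int(s.plot), s.label, s.method)))
    return StudyDesign(samples=ordered, pairing=pairing)


@dataclass
class TaxonAbundanceMatrix:
    """Taxon x fraction counts with taxonomy strings and fraction->tube mapping.

    ``counts`` is a DataFrame indexed by taxon id with fraction ids as
    columns; values are non-negative (integers for real sequencing data,
    reals allowed for noise-free expected counts).  ``taxonomy`` maps
    taxon id to a semicolon-delimited rank string.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    fraction_to_tube: Mapping[str, str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise ValidationError(f"duplicate taxon ids {dup}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts present")
        missing_tax = sorted(set(self.counts.index) - set(self.taxonomy.index))
        if missing_tax:
            raise ValidationError(f"taxa without taxonomy: {missing_tax}")
        unknown = sorted(set(self.counts.columns) - set(self.fraction_to_tube))
        if unknown:
            raise ValidationError(f"count columns for unknown fractions: {unknown}")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Per-fraction relative abundance p_ik; zero columns stay zero."""
        colsum = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.div(colsum.replace(0, np.nan), axis=1)
        return rel.fillna(0.0)

    def subset_taxa(self, taxa: Sequence[str]) -> "TaxonAbundanceMatrix":
        taxa = list(taxa)
        return TaxonAbundanceMatrix(
            counts=self.counts.loc[taxa].copy(),
            taxonomy=self.taxonomy.loc[taxa].copy(),
            fraction_to_tube=dict(self.fraction_to_tube),
            provenance={t: self.provenance.get(t, [t]) for t in taxa},
        )
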