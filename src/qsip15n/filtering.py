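"""ASV quality filtering, genus-level aggregation, and genus filters.

Filter order is fixed: ASV filter -> aggregate to genus -> genus-level
abundance/prevalence filters.  Each stage emits a report row so removals
are attributable to a rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import StudyDesign, TaxonAbundanceMatrix, ValidationError

_PLACEHOLDERS = {"", "uncultured", "unclassified", "unknown", "na", "nan"}
_RANK_NAMES = ["domain", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class FilterReport:
    """Per-rule removal tallies accumulated across pipeline stages."""

    rows: list[dict] = field(default_factory=list)

    def add(self, rule: str, removed: int, retained: int, detail: str = "") -> None:
        self.rows.append(
            {"rule": rule, "taxa_removed": removed, "taxa_retained": retained, "detail": detail}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "taxa_removed", "taxa_retained", "detail"])


@dataclass
class GenusTable:
    """Genus x fraction counts with per-genus ASV provenance."""

    counts: pd.DataFrame  # index: genus label
    provenance: Mapping[str, list[str]]
    fraction_to_tube: Mapping[str, str]

    @property
    def genera(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, genera: Sequence[str]) -> "GenusTable":
        genera = list(genera)
        return GenusTable(
            counts=self.counts.loc[genera].copy(),
            provenance={g: list(self.provenance[g]) for g in genera},
            fraction_to_tube=dict(self.fraction_to_tube),
        )


def parse_ranks(taxonomy: str, taxon_id: str = "?") -> list[str]:
    """Split a semicolon-delimited lineage into cleaned rank names.

    Accepts SILVA-style prefixes (``g__Bacillus``) or plain names;
    placeholders (empty, 'uncultured', 'unclassified', bare prefixes)
    become empty strings.  An unresolved rank may not be followed by a
    resolved one.
    """
    if not isinstance(taxonomy, str) or not taxonomy.strip():
        raise ValidationError(f"ASV {taxon_id!r}: empty taxonomy string")
    ranks = []
    for tok in taxonomy.split(";"):
        tok = tok.strip()
        if len(tok) > 2 and tok[1:3] == "__":
            tok = tok[3:]
        if tok.lower() in _PLACEHOLDERS:
            tok = ""
        ranks.append(tok)
    while ranks and ranks[-1] == "":
        ranks.pop()
    if any(r == "" for r in ranks):
        raise ValidationError(
            f"ASV {taxon_id!r}: unresolved rank followed by a resolved one in {taxonomy!r}"
        )
    if not ranks:
        raise ValidationError(f"ASV {taxon_id!r}: taxonomy {taxonomy!r} resolves no rank")
    return ranks


def genus_key_and_label(taxonomy: str, taxon_id: str = "?") -> tuple[tuple[str, ...], str]:
    """Genus identity (full 6-rank prefix) and display label.

    ASVs resolved to genus share a key iff their whole 6-rank lineage
    matches; ASVs unresolved at genus level are labeled by their finest
    resolved rank followed by ``gen.`` and keyed on that prefix, so the
    same family under different orders stays distinct.
    """
    ranks = parse_ranks(taxonomy, taxon_id)
    prefix = tuple(ranks[:6])
    if len(ranks) >= 6:
        return prefix, ranks[5]
    return prefix, f"{ranks[-1]} gen."


def filter_asvs(
    m: TaxonAbundanceMatrix,
    min_total: int = 200,
    min_fractions: int = 20,
    require_both: bool = True,
    report: FilterReport | None = None,
) -> TaxonAbundanceMatrix:
    """Remove low-quality ASVs by total count and fraction prevalence.

    Default (permissive) reading: an ASV is removed only when its total
    count is below ``min_total`` AND it occurs in fewer than
    ``min_fractions`` fractions.  ``require_both=False`` switches to the
    strict reading (either condition removes).
    """
    total = m.counts.sum(axis=1)
    nfrac = (m.counts > 0).sum(axis=1)
    low_total = total < min_total
    low_prev = nfrac < min_fractions
    removed = (low_total & low_prev) if require_both else (low_total | low_prev)
    keep = list(m.counts.index[~removed])
    if report is not None:
        report.add(
            f"asv_min_total_{min_total}_min_fractions_{min_fractions}"
            + ("_both" if require_both else "_either"),
            int(removed.sum()),
            len(keep),
        )
    return m.subset_taxa(keep)


def aggregate_to_genus(m: TaxonAbundanceMatrix) -> GenusTable:
    """Sum ASV counts into genus-level rows keyed on the full 6-rank lineage."""
    keys: dict[tuple[str, ...], list[str]] = {}
    labels: dict[tuple[str, ...], str] = {}
    for taxon_id in m.counts.index:
        key, label = genus_key_and_label(m.taxonomy.loc[taxon_id], taxon_id)
        keys.setdefault(key, []).append(taxon_id)
        labels[key] = label

    # Disambiguate display labels shared by distinct lineages.
    label_counts: dict[str, int] = {}
    for key in sorted(keys):
        label_counts[labels[key]] = label_counts.get(labels[key], 0) + 1
    seen: dict[str, int] = {}
    rows, provenance = [], {}
    for key in sorted(keys):
        label = labels[key]
        if label_counts[label] > 1:
            seen[label] = seen.get(label, 0) + 1
            parent = key[-2] if len(key) >= 2 else ""
            label = f"{label} ({parent or seen[label]})"
        rows.append((label, m.counts.loc[keys[key]].sum(axis=0)))
        provenance[label] = sorted(keys[key])
    counts = pd.DataFrame({lab: row for lab, row in rows}).T
    counts.columns = m.counts.columns
    return GenusTable(counts=counts, provenance=provenance, fraction_to_tube=m.fraction_to_tube)


def sample_relative_abundance(
    g: GenusTable,
    tube_fraction_totals: Mapping[str, pd.Series],
    tube_to_sample: Mapping[str, str],
) -> pd.DataFrame:
    """Copies-weighted per-sample genus relative abundance.

    For each tube, genus copies are the per-fraction relative read
    proportion times the fraction's qPCR total, summed over the analyzed
    fractions; dividing by the tube's total copies gives the genus's
    sample-level relative abundance.  Returns genus x sample_id.
    """
    out = {}
    for tube_id, totals in tube_fraction_totals.items():
        cols = [c for c in totals.index if c in g.counts.columns]
        if not cols:
            continue
        sub = g.counts[cols]
        colsum = sub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = sub.div(colsum.replace(0, np.nan), axis=1).fillna(0.0)
        copies = p.mul(totals.loc[cols], axis=1).sum(axis=1)
        tot = float(totals.loc[cols].sum())
        out[tube_to_sample[tube_id]] = copies / tot if tot > 0 else copies * 0.0
    return pd.DataFrame(out)


def filter_genera(
    g: GenusTable,
    design: StudyDesign,
    rel_abund: pd.DataFrame,
    tube_to_sample: Mapping[str, str],
    min_relabund: float = 0.0001,
    min_samples_per_site: int = 5,
    report: FilterReport | None = None,
) -> GenusTable:
    """Genus-level abundance and per-site prevalence filters.

    A genus is removed when its mean (across samples) copies-weighted
    relative abundance falls below ``min_relabund``, or when it is
    detected in fewer than ``min_samples_per_site`` plots at either
    site.  Detection in a plot means at least one read in at least one
    analyzed fraction of any of that plot's tubes.
    """
    mean_ra = rel_abund.mean(axis=1)
    low_ra = mean_ra < min_relabund

    sample_site_plot = {s.sample_id: (s.site, int(s.plot)) for s in design.samples}
    frac_sample = {
        fid: tube_to_sample[tid] for fid, tid in g.fraction_to_tube.items() if tid in tube_to_sample
    }
    present = g.counts > 0
    plot_presence: dict[tuple[str, int], pd.Series] = {}
    for fid in present.columns:
        sid = frac_sample.get(fid)
        if sid is None or sid not in sample_site_plot:
            continue
        key = sample_site_plot[sid]
        col = present[fid]
        plot_presence[key] = plot_presence.get(key, col * False) | col
    prev = pd.DataFrame(
        {site: pd.DataFrame({k: v for k, v in plot_presence.items() if k[0] == site}).sum(axis=1)
         for site in {k[0] for k in plot_presence}}
    )
    low_prev = (prev < min_samples_per_site).any(axis=1)
    low_prev = low_prev.reindex(g.counts.index, fill_value=True)

    keep = list(g.counts.index[~(low_ra.reindex(g.counts.index, fill_value=True) | low_prev)])
    if report is not None:
        report.add(f"genus_mean_relabund_lt_{min_relabund}", int(low_ra.sum()),
                   int((~low_ra).sum()))
        report.add(f"genus_prevalence_lt_{min_samples_per_site}_per_site", int(low_prev.sum()),
                   int((~low_prev).sum()))
        report.add("genus_filters_combined", len(g.counts.index) - len(keep), len(keep))
    return g.subset(keep)
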