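"""Weighted average buoyant density (WAD) and tube-level correction.

A taxon's WAD in a tube is the density of its DNA's center of mass
along the gradient, estimated from its 16S copy abundance per fraction
(read proportion x qPCR total).  Isotope assimilation shifts the WAD of
labeled samples upward relative to the natural-abundance (unlabeled)
reference; small tube-to-tube offsets in the CsCl calibration are
removed using the taxa with the smallest apparent shifts as internal
standards.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import TubeGradient

log = logging.getLogger(__name__)

DENSITY_WINDOW = (1.67, 1.74)  # g/mL, the sequenced gradient region


def select_fractions(
    t: TubeGradient, window: tuple[float, float] = DENSITY_WINDOW
) -> TubeGradient:
    """Retain fractions with density inside the closed analysis window.

    Tubes retaining fewer than 3 fractions are flagged ``unusable``
    rather than raising, so a study-level run can report and skip them.
    """
    lo, hi = window
    kept = tuple(f for f in t.fractions if lo <= f.density <= hi)
    if len(kept) < 3:
        warnings.warn(f"tube {t.tube_id!r}: only {len(kept)} fractions in window; unusable")
        return TubeGradient(t.tube_id, t.sample_id, kept, unusable=True)
    return replace(t, fractions=kept)


def taxon_fraction_copies(rel_abund: np.ndarray, total_copies: np.ndarray) -> np.ndarray:
    """Per-fraction 16S copies of one taxon: y_k = p_k * f_k."""
    rel_abund = np.asarray(rel_abund, dtype=float)
    total_copies = np.asarray(total_copies, dtype=float)
    if rel_abund.shape != total_copies.shape:
        raise ValueError(
            f"length mismatch: rel_abund {rel_abund.shape} vs total_copies {total_copies.shape}"
        )
    return rel_abund * total_copies


def weighted_average_density(copies: np.ndarray, densities: np.ndarray) -> float:
    """WAD = sum(x_k * y_k) / sum(y_k); NaN when the taxon is absent."""
    copies = np.asarray(copies, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if copies.shape != densities.shape:
        raise ValueError("copies and densities must align")
    total = copies.sum()
    if total <= 0:
        return float("nan")
    return float((densities * copies).sum() / total)


def wad_table(
    tubes: Sequence[TubeGradient],
    genus_counts: pd.DataFrame,
    fraction_to_tube: Mapping[str, str],
) -> pd.DataFrame:
    """Per-(genus, tube) WAD, copies recovered and detection count.

    ``genus_counts`` is genus x fraction reads; fraction qPCR totals and
    densities come from ``tubes`` (already window-selected).  Returns a
    long DataFrame (genus, tube_id, wad, copies_recovered,
    n_fractions_detected); WAD is NaN where no copies were recovered.
    """
    frames = []
    for t in tubes:
        if t.unusable or not t.fractions:
            continue
        cols = [fid for fid in t.fraction_ids if fid in genus_counts.columns]
        if not cols:
            continue
        sub = genus_counts[cols].to_numpy(dtype=float)
        dens = np.array([f.density for f in t.fractions if f.fraction_id in set(cols)])
        totals = np.array([f.total_copies for f in t.fractions if f.fraction_id in set(cols)])
        colsum = sub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(colsum > 0, sub / colsum, 0.0)
        copies = p * totals  # genus x fraction 16S copies
        recovered = copies.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            wad = np.where(recovered > 0, (copies * dens).sum(axis=1) / recovered, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "genus": genus_counts.index,
                    "tube_id": t.tube_id,
                    "wad": wad,
                    "copies_recovered": recovered,
                    "n_fractions_detected": (sub > 0).sum(axis=1),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["genus", "tube_id", "wad", "copies_recovered", "n_fractions_detected"]
        )
    return pd.concat(frames, ignore_index=True)


def light_wad(wads: pd.DataFrame, unlabeled_tubes: Sequence[str]) -> pd.DataFrame:
    """Natural-abundance WAD per genus: mean over unlabeled tubes.

    Returns (genus, w_light, n_tubes); genera absent from every
    unlabeled tube are dropped (they cannot enter EAF estimation) and
    logged.
    """
    sub = wads[wads["tube_id"].isin(set(unlabeled_tubes))].dropna(subset=["wad"])
    out = (
        sub.groupby("genus")["wad"].agg(w_light="mean", n_tubes="count").reset_index()
    )
    missing = set(wads["genus"].unique()) - set(out["genus"])
    if missing:
        log.warning(
            "%d genera absent from all unlabeled tubes; dropped from enrichment: %s",
            len(missing),
            sorted(missing)[:10],
        )
    return out


def wad_shifts(
    wads: pd.DataFrame,
    pairing_tubes: Mapping[str, str],
) -> pd.DataFrame:
    """Raw WAD shift per (genus, labeled tube) against its paired control tube.

    ``pairing_tubes`` maps labeled tube_id -> unlabeled tube_id of the
    same plot.  Rows where either WAD is undefined are dropped.
    """
    wide = wads.pivot(index="genus", columns="tube_id", values="wad")
    rows = []
    for lab_tube, ctl_tube in pairing_tubes.items():
        if lab_tube not in wide.columns or ctl_tube not in wide.columns:
            continue
        d = wide[lab_tube] - wide[ctl_tube]
        d = d.dropna()
        rows.append(pd.DataFrame({"genus": d.index, "tube_id": lab_tube, "raw_dwad": d.values}))
    if not rows:
        return pd.DataFrame(columns=["genus", "tube_id", "raw_dwad"])
    return pd.concat(rows, ignore_index=True)


def tube_correction(shifts: pd.DataFrame, n_ref: int = 50) -> pd.DataFrame:
    """Remove per-tube density-calibration offsets from raw WAD shifts.

    The reference set is the ``n_ref`` genera with the smallest absolute
    mean raw shift across all labeled tubes (preferring genera observed
    in every labeled tube); each labeled tube's offset is the median raw
    shift of reference genera detected in that tube, and the corrected
    shift is raw minus offset.  Adds columns ``tube_offset``,
    ``corrected_dwad`` and ``is_reference``.
    """
    if shifts.empty:
        out = shifts.copy()
        out["tube_offset"] = []
        out["corrected_dwad"] = []
        out["is_reference"] = []
        return out
    n_tubes = shifts["tube_id"].nunique()
    per_genus = shifts.groupby("genus")["raw_dwad"].agg(["mean", "count"])
    complete = per_genus[per_genus["count"] == n_tubes]
    pool = complete if len(complete) >= n_ref else per_genus
    if len(pool) < n_ref:
        warnings.warn(
            f"only {len(pool)} genera available for tube correction (requested {n_ref}); using all"
        )
    ref = pool["mean"].abs().sort_values(kind="mergesort").index[:n_ref]
    ref = set(ref)

    offsets = (
        shifts[shifts["genus"].isin(ref)].groupby("tube_id")["raw_dwad"].median()
    )
    out = shifts.copy()
    out["tube_offset"] = out["tube_id"].map(offsets)
    missing_tubes = out["tube_offset"].isna()
    if missing_tubes.any():
        warnings.warn(
            f"tubes without reference genera get offset 0: "
            f"{sorted(out.loc[missing_tubes, 'tube_id'].unique())}"
        )
        out.loc[missing_tubes, "tube_offset"] = 0.0
    out["corrected_dwad"] = out["raw_dwad"] - out["tube_offset"]
    out["is_reference"] = out["genus"].isin(ref)
    return out
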