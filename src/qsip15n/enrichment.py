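"""Conversion of WAD shifts to :sup:`15`\\ N excess atom fraction (EAF).

The chain follows the standard qSIP model: the natural-abundance WAD of
a taxon fixes its GC content via the linear GC-density relationship; GC
fixes the average molecular weight per nucleotide of unlabeled DNA and
the maximum weight gain attainable when every N atom is :sup:`15`\\ N.
The observed relative WAD shift of the labeled sample scales molecular
weight proportionally, and the realised fraction of the maximal gain —
net of the 0.3663% natural abundance of :sup:`15`\\ N — is the excess
atom fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IsotopeConstants:
    """Linear coefficients of the qSIP :sup:`15`\\ N formula chain.

    Units: densities g/mL, molecular weights g/mol per average
    nucleotide, GC as a proportion in [0, 1].
    """

    gc_slope: float = 0.083506  # g/mL per unit GC
    gc_intercept: float = 1.646057  # g/mL at GC = 0
    mw_light_slope: float = 0.496  # g/mol per unit GC
    mw_light_intercept: float = 307.691  # g/mol at GC = 0
    heavy_max_slope: float = 0.5024  # g/mol per unit GC, max 15N gain
    heavy_max_intercept: float = 3.517  # g/mol at GC = 0
    nat_abund_15n: float = 0.003663  # atom fraction of 15N at natural abundance

    def __post_init__(self) -> None:
        for name in (
            "gc_slope",
            "gc_intercept",
            "mw_light_slope",
            "mw_light_intercept",
            "heavy_max_slope",
            "heavy_max_intercept",
            "nat_abund_15n",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"IsotopeConstants.{name} must be positive")


DEFAULT_CONSTANTS = IsotopeConstants()


def gc_from_light_wad(w_light, c: IsotopeConstants = DEFAULT_CONSTANTS):
    """GC content from natural-abundance WAD; clipped to [0, 1] with a warning."""
    gc = (np.asarray(w_light, dtype=float) - c.gc_intercept) / c.gc_slope
    if np.any((gc < 0) | (gc > 1)):
        log.warning("GC outside [0,1] for some taxa; clipping")
    out = np.clip(gc, 0.0, 1.0)
    return float(out) if np.isscalar(w_light) or np.ndim(w_light) == 0 else out


def molecular_weights(gc, c: IsotopeConstants = DEFAULT_CONSTANTS):
    """(m_light, m_heavy_max): unlabeled and maximally 15N-labeled MW per nucleotide."""
    gc = np.asarray(gc, dtype=float)
    m_light = c.mw_light_slope * gc + c.mw_light_intercept
    m_heavy_max = m_light + c.heavy_max_slope * gc + c.heavy_max_intercept
    if gc.ndim == 0:
        return float(m_light), float(m_heavy_max)
    return m_light, m_heavy_max


def eaf_15n(w_lab, w_light, gc, c: IsotopeConstants = DEFAULT_CONSTANTS):
    """Raw excess atom fraction 15N from the labeled/light WAD pair.

    m_lab = m_light * w_lab / w_light;
    EAF = (m_lab - m_light) / (m_heavy_max - m_light) * (1 - nat_abund).
    Negative values (labeled WAD below the reference) pass through;
    clamping is a separate, reported step.
    """
    w_lab = np.asarray(w_lab, dtype=float)
    w_light = np.asarray(w_light, dtype=float)
    m_light, m_heavy_max = molecular_weights(gc, c)
    m_lab = m_light * (w_lab / w_light)
    raw = (m_lab - m_light) / (m_heavy_max - m_light) * (1.0 - c.nat_abund_15n)
    return float(raw) if raw.ndim == 0 else raw


def invert_eaf_15n(eaf, w_light, gc, c: IsotopeConstants = DEFAULT_CONSTANTS):
    """Labeled WAD that yields a given EAF — the forward model's inverse.

    Used by the simulator to place labeled taxa on the gradient and by
    self-consistency tests: ``eaf_15n(invert_eaf_15n(e, w, g), w, g) == e``.
    """
    eaf = np.asarray(eaf, dtype=float)
    w_light = np.asarray(w_light, dtype=float)
    m_light, m_heavy_max = molecular_weights(gc, c)
    m_lab = m_light + eaf / (1.0 - c.nat_abund_15n) * (m_heavy_max - m_light)
    out = w_light * m_lab / m_light
    return float(out) if out.ndim == 0 else out


def clamp_negative(eaf, report: bool = True):
    """Replace negative EAF estimates with zero (reporting how many)."""
    arr = np.asarray(eaf, dtype=float)
    n_clamped = int(np.sum(arr < 0))
    if report and n_clamped:
        log.info("clamped %d negative EAF values to zero", n_clamped)
    out = np.maximum(arr, 0.0)
    return (float(out) if arr.ndim == 0 else out), n_clamped


def percent_n_assimilated(eafs, rel_abunds):
    """Each taxon's share of community N assimilation.

    P_i = RA_i * E_i / sum_j RA_j * E_j; sums to 1 when any product is
    positive, otherwise all zeros (with a warning).
    """
    eafs = np.asarray(eafs, dtype=float)
    rel_abunds = np.asarray(rel_abunds, dtype=float)
    if eafs.shape != rel_abunds.shape:
        raise ValueError("eafs and rel_abunds must align")
    if np.any(rel_abunds < 0):
        raise ValueError("relative abundances must be >= 0")
    prod = rel_abunds * eafs
    total = prod.sum()
    if total <= 0:
        log.warning("all abundance x EAF products are zero; %%N undefined, returning zeros")
        return np.zeros_like(prod)
    return prod / total
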