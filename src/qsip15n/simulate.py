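"""Forward simulator of a paired field/lab :sup:`15`\\ N qSIP experiment.

Generates a synthetic community (GC content, abundances, true per-taxon
enrichment), places each taxon's DNA on a CsCl gradient by inverting the
enrichment formula chain, spreads it over fraction bins with a Gaussian
kernel, and adds the experiment's noise sources: per-tube density
offsets, multiplicative qPCR noise, and multinomial sequencing counts.
The emitted tables are pipeline-ready and come with a truth table for
parameter-recovery tests.

Default parameters mirror the emulated study: 2 sites x 7 plots, one
pre-incubation control plus field and lab labeled tubes per plot, ~25
fractions per tube with the 1.67-1.74 g/mL window sequenced, and a
lab-to-field enrichment map with slope 0.81 and intercept 0.01.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import GradientFraction, SampleMeta, TaxonAbundanceMatrix, TubeGradient
from .enrichment import DEFAULT_CONSTANTS, IsotopeConstants, invert_eaf_15n
from . import io as qio


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward model.

    The GC distribution is a scaled Beta reflecting GC-rich soil
    communities (mean ~0.60); true lab enrichment is zero-inflated with
    a right-skewed positive component whose mean (~0.19) makes the
    lab-to-field map's aggregate lab excess consistent with the paired
    design it emulates.
    """

    n_taxa: int = 300
    gc_beta: tuple[float, float] = (7.0, 3.0)
    gc_range: tuple[float, float] = (0.25, 0.75)
    abund_sigma: float = 1.0  # lognormal sigma of baseline abundances
    eaf_zero_prob: float = 0.2  # zero-inflation of true lab EAF
    eaf_beta: tuple[float, float] = (2.0, 3.0)
    eaf_max: float = 0.6
    field_slope: float = 0.81  # lab -> field EAF map
    field_intercept: float = 0.01
    field_noise_sd: float = 0.02  # taxon-level scatter around the map
    sites: tuple[str, ...] = ("Valley", "Ridge")
    n_plots: int = 7
    fractions_per_tube: int = 25
    density_range: tuple[float, float] = (1.61, 1.78)
    analysis_window: tuple[float, float] = (1.67, 1.74)
    kernel_sd: float = 0.006  # g/mL within-taxon density spread
    tube_offset_sd: float = 0.002  # g/mL per-tube calibration offset
    qpcr_cv: float = 0.1  # multiplicative lognormal CV on fraction totals
    seq_depth: int | None = 10_000  # reads per sequenced fraction; None = exact proportions
    total_copies_scale: float = 1e8  # 16S copies per tube at abundance 1
    asvs_per_genus: int = 1
    seed: int = 0
    constants: IsotopeConstants = field(default_factory=IsotopeConstants)

    def validate(self) -> None:
        if self.n_taxa < 1 or self.n_plots < 1 or self.fractions_per_tube < 3:
            raise ValueError("n_taxa, n_plots, fractions_per_tube out of range")
        for name in ("kernel_sd", "total_copies_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tube_offset_sd", "qpcr_cv", "field_noise_sd", "eaf_zero_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.eaf_zero_prob <= 1):
            raise ValueError("eaf_zero_prob must be in [0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study.

    ``taxa``: per-genus gc, abundance and true EAF per method;
    ``tube_offsets``: tube_id -> density offset (g/mL);
    ``config``: the generating configuration (with seed).
    """

    taxa: pd.DataFrame
    tube_offsets: dict[str, float]
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        return self.taxa.copy()


def _taxonomy_string(i: int) -> str:
    return (
        "d__Bacteria"
        f";p__Phylum{i % 10:02d}"
        f";c__Class{i % 20:02d}"
        f";o__Order{i % 40:02d}"
        f";f__Family{i % 80:02d}"
        f";g__Genus{i:04d}"
    )


def genus_label(i: int) -> str:
    return f"Genus{i:04d}"


def simulate_taxa(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SimulationTruth:
    """Draw the community: GC, abundances, and true enrichment per method."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_taxa
    gc = cfg.gc_range[0] + (cfg.gc_range[1] - cfg.gc_range[0]) * rng.beta(*cfg.gc_beta, size=n)
    abund = rng.lognormal(mean=0.0, sigma=cfg.abund_sigma, size=n)
    abund /= abund.sum()
    zero = rng.random(n) < cfg.eaf_zero_prob
    eaf_lab = np.where(zero, 0.0, cfg.eaf_max * rng.beta(*cfg.eaf_beta, size=n))
    noise = rng.normal(0.0, cfg.field_noise_sd, size=n) if cfg.field_noise_sd > 0 else 0.0
    eaf_field = np.maximum(cfg.field_slope * eaf_lab + cfg.field_intercept + noise, 0.0)
    taxa = pd.DataFrame(
        {
            "genus": [genus_label(i) for i in range(n)],
            "taxonomy": [_taxonomy_string(i) for i in range(n)],
            "gc": gc,
            "abundance": abund,
            "eaf_lab": eaf_lab,
            "eaf_field": eaf_field,
        }
    ).set_index("genus", drop=False)
    return SimulationTruth(taxa=taxa, tube_offsets={}, config=cfg)


def _bin_edges(cfg: SimulationConfig) -> np.ndarray:
    return np.linspace(cfg.density_range[0], cfg.density_range[1], cfg.fractions_per_tube + 1)


def _gaussian_bin_mass(centers: np.ndarray, edges: np.ndarray, sd: float) -> np.ndarray:
    """Mass of N(center, sd) DNA in each bin; taxa x bins."""
    from scipy.stats import norm

    z = (edges[None, :] - centers[:, None]) / sd
    cdf = norm.cdf(z)
    return np.diff(cdf, axis=1)


def true_centers(
    truth: SimulationTruth, method: str | None, c: IsotopeConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Per-taxon gradient center density: light for controls, shifted when labeled."""
    cfg = truth.config
    gc = truth.taxa["gc"].to_numpy()
    w_light = c.gc_intercept + c.gc_slope * gc
    if method is None:
        return w_light
    eaf = truth.taxa[f"eaf_{method}"].to_numpy()
    return invert_eaf_15n(eaf, w_light, gc, c)


def simulate_tube(
    truth: SimulationTruth,
    sample: SampleMeta,
    tube_id: str,
    rng: np.random.Generator,
) -> tuple[TubeGradient, pd.DataFrame, float]:
    """Simulate one tube: gradient fractions plus the ASV count slice.

    Returns the TubeGradient (all fractions, with qPCR noise applied to
    the totals), a counts DataFrame (ASV x fraction; zero outside the
    sequenced window), and the tube's true density offset.
    """
    cfg = truth.config
    c = cfg.constants
    edges = _bin_edges(cfg)
    centers_d = 0.5 * (edges[:-1] + edges[1:])
    offset = float(rng.normal(0.0, cfg.tube_offset_sd)) if cfg.tube_offset_sd > 0 else 0.0

    method = sample.method if sample.label == "labeled" else None
    taxon_centers = true_centers(truth, method, c) + offset
    mass = _gaussian_bin_mass(taxon_centers, edges, cfg.kernel_sd)  # taxa x bins
    abund = truth.taxa["abundance"].to_numpy()
    copies = abund[:, None] * cfg.total_copies_scale * mass

    totals_true = copies.sum(axis=0)
    if cfg.qpcr_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.qpcr_cv**2))
        totals = totals_true * rng.lognormal(mean=0.0, sigma=sigma, size=len(totals_true))
    else:
        totals = totals_true.copy()

    lo, hi = cfg.analysis_window
    in_window = (centers_d >= lo) & (centers_d <= hi)

    # spread genus copies over its ASVs (equal split keeps truth at genus level)
    n_asv = cfg.asvs_per_genus
    asv_ids, asv_copies = [], []
    for i, genus in enumerate(truth.taxa["genus"]):
        for j in range(n_asv):
            asv_ids.append(f"ASV_{i:04d}_{j}" if n_asv > 1 else f"ASV_{i:04d}")
            asv_copies.append(copies[i] / n_asv)
    asv_copies = np.asarray(asv_copies)

    counts = np.zeros_like(asv_copies)
    for k in np.flatnonzero(in_window):
        col = asv_copies[:, k]
        tot = col.sum()
        if tot <= 0:
            continue
        p = col / tot
        if cfg.seq_depth is None:
            counts[:, k] = p * 1e6  # expected reads at effectively infinite depth
        else:
            counts[:, k] = rng.multinomial(cfg.seq_depth, p)

    fraction_ids = [f"{tube_id}:F{k:02d}" for k in range(len(centers_d))]
    fractions = [
        GradientFraction(fraction_ids[k], float(centers_d[k]), float(totals[k]))
        for k in range(len(centers_d))
    ]
    tube = TubeGradient(tube_id, sample.sample_id, tuple(fractions))
    counts_df = pd.DataFrame(counts, index=asv_ids, columns=fraction_ids)
    return tube, counts_df, offset


def study_samples(cfg: SimulationConfig) -> list[SampleMeta]:
    """The full 2 sites x n_plots x (pre + field + lab) sample list."""
    metas = []
    for site in cfg.sites:
        for plot in range(1, cfg.n_plots + 1):
            metas.append(SampleMeta(f"{site}_p{plot}_pre", site, "pre", plot, "unlabeled"))
            for method in ("field", "lab"):
                metas.append(SampleMeta(f"{site}_p{plot}_{method}", site, method, plot, "labeled"))
    return metas


def simulate_study(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> tuple[list[TubeGradient], TaxonAbundanceMatrix, list[SampleMeta], SimulationTruth]:
    """Simulate the whole paired study, optionally writing pipeline input files.

    Deterministic given ``cfg.seed``: the same configuration always
    yields identical tables (and byte-identical files).
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    rng_taxa = np.random.default_rng(root.spawn(1)[0])
    truth = simulate_taxa(cfg, rng_taxa)

    metas = study_samples(cfg)
    tubes: list[TubeGradient] = []
    slices: list[pd.DataFrame] = []
    tube_seeds = root.spawn(1 + len(metas))[1:]
    for idx, (sample, ss) in enumerate(zip(metas, tube_seeds)):
        tube_id = f"T{idx:02d}"
        tube, counts, offset = simulate_tube(truth, sample, tube_id, np.random.default_rng(ss))
        tubes.append(tube)
        slices.append(counts)
        truth.tube_offsets[tube_id] = offset

    counts = pd.concat(slices, axis=1)
    taxonomy = pd.Series(
        np.repeat(truth.taxa["taxonomy"].to_numpy(), cfg.asvs_per_genus),
        index=counts.index,
        name="taxonomy",
    )
    frac_to_tube = {fid: t.tube_id for t in tubes for fid in t.fraction_ids}
    matrix = TaxonAbundanceMatrix(counts=counts, taxonomy=taxonomy, fraction_to_tube=frac_to_tube)

    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")
        out.mkdir(parents=True, exist_ok=True)
        qio.write_fraction_table(tubes, out / "fractions.tsv")
        qio.write_taxon_counts(matrix, out / "counts.tsv", out / "taxonomy.tsv")
        qio.write_sample_table(metas, out / "samples.tsv")
        truth_df = truth.taxa.reset_index(drop=True).copy()
        qio.write_result_table(truth_df, out / "truth.tsv")
        offsets = pd.DataFrame(
            sorted(truth.tube_offsets.items()), columns=["tube_id", "offset"]
        )
        qio.write_result_table(offsets, out / "tube_offsets.tsv")
        cfg_rows = pd.DataFrame(
            [(k, v) for k, v in asdict(cfg).items()], columns=["parameter", "value"]
        )
        qio.write_result_table(cfg_rows, out / "sim_config.tsv")

    return tubes, matrix, metas, truth
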