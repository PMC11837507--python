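"""The qSIP estimation model: gradient data in, per-genus enrichment out.

:class:`NitrogenQsip` bundles the pipeline stages — taxon filtering,
genus aggregation, fraction-window selection, weighted average density,
tube correction, excess atom fraction and %N assimilated — behind a
statsmodels-style ``Model.fit() -> Results`` interface.  The results
object carries the per-(genus, site, method, plot) estimates and hangs
the method-comparison regression and per-genus tests off them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as qio
from .comparison import PassingBablok, PassingBablokResults, genus_group_test, significance_tier
from .datatypes import (
    DesignError,
    SampleMeta,
    StudyDesign,
    TaxonAbundanceMatrix,
    TubeGradient,
    validate_design,
)
from .enrichment import (
    DEFAULT_CONSTANTS,
    IsotopeConstants,
    clamp_negative,
    eaf_15n,
    gc_from_light_wad,
    percent_n_assimilated,
)
from .filtering import (
    FilterReport,
    aggregate_to_genus,
    filter_asvs,
    filter_genera,
    sample_relative_abundance,
)
from .wad import (
    DENSITY_WINDOW,
    light_wad,
    select_fractions,
    tube_correction,
    wad_shifts,
    wad_table,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and constants of a pipeline run (defaults = study values)."""

    asv_min_total: int = 200
    asv_min_fractions: int = 20
    asv_require_both: bool = True
    genus_min_relabund: float = 0.0001
    genus_min_samples_per_site: int = 5
    density_window: tuple[float, float] = DENSITY_WINDOW
    n_ref_genera: int = 50
    apply_tube_correction: bool = True
    bootstrap_b: int = 1999
    bootstrap_seed: int = 0
    pb_estimator: str = "equivariant"
    constants: IsotopeConstants = dc_field(default_factory=IsotopeConstants)


class NitrogenQsip:
    """15N-qSIP model for one paired labeling study.

    Parameters
    ----------
    tubes : sequence of TubeGradient
        All gradient tubes (densities + qPCR totals per fraction).
    counts : TaxonAbundanceMatrix
        ASV x fraction sequence counts with taxonomy.
    design : StudyDesign or sequence of SampleMeta
        Sample metadata; a raw metadata list is validated into a design.
    config : PipelineConfig
        Filter thresholds, density window, reference-set size, constants.
    """

    def __init__(
        self,
        tubes: Sequence[TubeGradient],
        counts: TaxonAbundanceMatrix,
        design: StudyDesign | Sequence[SampleMeta],
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig()
        self.design = design if isinstance(design, StudyDesign) else validate_design(list(design))
        self.tubes = list(tubes)
        self.counts = counts

        sample_ids = {s.sample_id for s in self.design.samples}
        tube_samples = {t.sample_id for t in self.tubes}
        missing = sorted(tube_samples - sample_ids)
        if missing:
            raise DesignError(f"tubes reference samples absent from metadata: {missing}")
        self.sample_to_tube = {t.sample_id: t.tube_id for t in self.tubes}
        self.tube_to_sample = {t.tube_id: t.sample_id for t in self.tubes}

    @classmethod
    def from_files(
        cls,
        fractions: str | Path,
        counts: str | Path,
        taxonomy: str | Path,
        samples: str | Path,
        config: PipelineConfig | None = None,
        sep: str | None = None,
    ) -> "NitrogenQsip":
        tubes = qio.read_fraction_table(fractions, sep=sep)
        metas = qio.read_sample_table(samples, sep=sep)
        matrix = qio.read_taxon_counts(counts, taxonomy, tubes, sep=sep)
        return cls(tubes, matrix, metas, config)

    def fit(self) -> "QsipResults":
        """Run the full estimation chain and return the results object."""
        cfg = self.config
        report = FilterReport()

        filtered = filter_asvs(
            self.counts,
            min_total=cfg.asv_min_total,
            min_fractions=cfg.asv_min_fractions,
            require_both=cfg.asv_require_both,
            report=report,
        )
        genus = aggregate_to_genus(filtered)

        window_tubes = [select_fractions(t, cfg.density_window) for t in self.tubes]
        usable = [t for t in window_tubes if not t.unusable]
        dropped = [t.tube_id for t in window_tubes if t.unusable]
        if dropped:
            log.warning("tubes unusable after window selection: %s", dropped)

        tube_totals = {
            t.tube_id: pd.Series(t.total_copies, index=t.fraction_ids) for t in usable
        }
        rel_abund = sample_relative_abundance(genus, tube_totals, self.tube_to_sample)
        genus = filter_genera(
            genus,
            self.design,
            rel_abund,
            self.tube_to_sample,
            min_relabund=cfg.genus_min_relabund,
            min_samples_per_site=cfg.genus_min_samples_per_site,
            report=report,
        )
        rel_abund = rel_abund.loc[genus.genera]

        wads = wad_table(usable, genus.counts, genus.fraction_to_tube)

        unlabeled_tubes = [
            self.sample_to_tube[s.sample_id]
            for s in self.design.unlabeled
            if s.sample_id in self.sample_to_tube
        ]
        lw = light_wad(wads, unlabeled_tubes).set_index("genus")

        pairing_tubes = {
            self.sample_to_tube[lab]: self.sample_to_tube[ctl]
            for lab, ctl in self.design.pairing.items()
            if lab in self.sample_to_tube and ctl in self.sample_to_tube
        }
        shifts = wad_shifts(wads, pairing_tubes)
        if cfg.apply_tube_correction:
            shifts = tube_correction(shifts, n_ref=cfg.n_ref_genera)
        else:
            # identifiability runs on gradients known to share one calibration
            shifts = shifts.copy()
            shifts["tube_offset"] = 0.0
            shifts["corrected_dwad"] = shifts["raw_dwad"]
            shifts["is_reference"] = False

        # assemble per-(genus, labeled sample) enrichment rows
        rows = shifts.merge(lw["w_light"], on="genus", how="inner")
        rows["sample_id"] = rows["tube_id"].map(self.tube_to_sample)
        meta_df = pd.DataFrame(
            [
                {"sample_id": s.sample_id, "site": s.site, "method": s.method, "plot": s.plot}
                for s in self.design.labeled
            ]
        )
        rows = rows.merge(meta_df, on="sample_id", how="inner")
        rows["gc"] = gc_from_light_wad(rows["w_light"].to_numpy(), cfg.constants)
        rows["w_lab"] = rows["w_light"] + rows["corrected_dwad"]
        rows["eaf_raw"] = eaf_15n(
            rows["w_lab"].to_numpy(), rows["w_light"].to_numpy(), rows["gc"].to_numpy(), cfg.constants
        )
        rows["eaf"], n_clamped = clamp_negative(rows["eaf_raw"].to_numpy())
        report.add("eaf_negative_clamped_values", n_clamped, int((rows["eaf"] > 0).sum()))

        ra_long = rel_abund.reset_index(names="genus").melt(
            id_vars="genus", var_name="sample_id", value_name="rel_abund"
        )
        rows = rows.merge(ra_long, on=["genus", "sample_id"], how="left")
        rows["rel_abund"] = rows["rel_abund"].fillna(0.0)

        rows["pct_n"] = 0.0
        for sid, grp in rows.groupby("sample_id"):
            rows.loc[grp.index, "pct_n"] = percent_n_assimilated(
                grp["eaf"].to_numpy(), grp["rel_abund"].to_numpy()
            )

        eaf = rows[
            [
                "genus", "site", "method", "plot", "sample_id", "gc", "w_light", "w_lab",
                "raw_dwad", "tube_offset", "corrected_dwad", "eaf_raw", "eaf",
                "rel_abund", "pct_n",
            ]
        ].sort_values(["site", "method", "plot", "genus"], kind="mergesort").reset_index(drop=True)

        return QsipResults(
            model=self,
            eaf=eaf,
            wads=wads,
            shifts=shifts,
            light=lw.reset_index(),
            filter_report=report.to_frame(),
            dropped_tubes=dropped,
        )


@dataclass
class QsipResults:
    """Fitted per-genus enrichment estimates and downstream comparisons.

    Attributes
    ----------
    eaf : DataFrame
        One row per (genus, site, method, plot): gc, w_light, w_lab,
        raw/corrected WAD shift, raw and clamped EAF, sample relative
        abundance and %N assimilated.
    wads, shifts, light : DataFrame
        Stage outputs (per-tube WADs, corrected shifts, light WADs).
    filter_report : DataFrame
        Removal tallies per filtering rule.
    """

    model: NitrogenQsip
    eaf: pd.DataFrame
    wads: pd.DataFrame
    shifts: pd.DataFrame
    light: pd.DataFrame
    filter_report: pd.DataFrame
    dropped_tubes: list[str]

    @property
    def genera(self) -> list[str]:
        return sorted(self.eaf["genus"].unique())

    def genus_medians(self, metric: str = "eaf", scope: str = "both") -> pd.DataFrame:
        """Per-genus median of ``metric`` across plots, wide by method.

        ``scope`` is a site name or 'both' (plots from both sites pooled
        before taking the median, matching the study-level comparison).
        """
        df = self.eaf if scope == "both" else self.eaf[self.eaf["site"] == scope]
        if df.empty:
            raise ValueError(f"no rows for scope {scope!r}")
        med = df.groupby(["genus", "method"])[metric].median().unstack("method")
        return med.dropna()

    def compare_methods(
        self,
        metric: str = "eaf",
        scope: str = "both",
        n_boot: int | None = None,
        seed: int | None = None,
        estimator: str | None = None,
    ) -> PassingBablokResults:
        """Passing-Bablok regression of field on lab genus medians."""
        cfg = self.model.config
        med = self.genus_medians(metric=metric, scope=scope)
        pb = PassingBablok(
            med["lab"].to_numpy(),
            med["field"].to_numpy(),
            estimator=estimator or cfg.pb_estimator,
        )
        return pb.fit(
            n_boot=cfg.bootstrap_b if n_boot is None else n_boot,
            seed=cfg.bootstrap_seed if seed is None else seed,
        )

    def comparison_table(
        self, scopes: Sequence[str] = ("both",), metrics: Sequence[str] = ("eaf", "pct_n"),
        n_boot: int | None = None, seed: int | None = None,
    ) -> pd.DataFrame:
        rows = []
        for scope in scopes:
            for metric in metrics:
                fit = self.compare_methods(metric=metric, scope=scope, n_boot=n_boot, seed=seed)
                rows.append(
                    {
                        "scope": scope,
                        "metric": metric,
                        "slope": fit.slope,
                        "slope_lo": fit.slope_ci[0],
                        "slope_hi": fit.slope_ci[1],
                        "intercept": fit.intercept,
                        "intercept_lo": fit.intercept_ci[0],
                        "intercept_hi": fit.intercept_ci[1],
                        "pearson_r": fit.pearson_r,
                        "n_genera": fit.n,
                        "proportional_difference": fit.proportional_difference,
                        "constant_difference": fit.constant_difference,
                    }
                )
        return pd.DataFrame(rows)

    def genus_tests(self, metric: str = "eaf", per_site: bool = True) -> pd.DataFrame:
        """One-way ANOVA (field vs lab, n = plots per method) per genus.

        Returns genus, site, F, p and the significance tier marker.
        """
        rows = []
        groups = ["site"] if per_site else []
        for keys, grp in self.eaf.groupby(groups + ["genus"]) if groups else (
            ((g,), sub) for g, sub in self.eaf.groupby("genus")
        ):
            sub = grp
            a = sub.loc[sub["method"] == "field", metric].to_numpy()
            b = sub.loc[sub["method"] == "lab", metric].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            f, p = genus_group_test(a, b)
            row = {"genus": keys[-1] if groups else keys[0], "F": f, "p": p,
                   "tier": significance_tier(p)}
            if groups:
                row["site"] = keys[0]
            rows.append(row)
        cols = ["genus", "site", "F", "p", "tier"] if per_site else ["genus", "F", "p", "tier"]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        eaf = self.eaf
        lines = [
            "15N-qSIP enrichment summary",
            "=" * 44,
            f"genera retained        {eaf['genus'].nunique()}",
            f"labeled samples        {eaf['sample_id'].nunique()}",
            f"tubes dropped (window) {len(self.dropped_tubes)}",
            f"negative EAF clamped   "
            f"{int((eaf['eaf_raw'] < 0).sum())} of {len(eaf)} rows",
            "",
            "median EAF by site and method:",
        ]
        med = eaf.groupby(["site", "method"])["eaf"].median()
        for (site, method), v in med.items():
            lines.append(f"  {site:8s} {method:6s} {v:8.4f}")
        return "\n".join(lines)

    def to_directory(self, out_dir: str | Path, write_comparison: bool = True) -> None:
        """Write the standard result bundle (eaf.tsv, wad.tsv, ...)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qio.write_result_table(self.eaf, out / "eaf.tsv")
        qio.write_result_table(self.wads, out / "wad.tsv")
        qio.write_result_table(self.shifts, out / "wad_shifts.tsv")
        qio.write_result_table(self.light, out / "light_wad.tsv")
        qio.write_result_table(self.filter_report, out / "filter_report.tsv")
        if write_comparison:
            qio.write_result_table(self.comparison_table(), out / "comparison.tsv")
            qio.write_result_table(self.genus_tests(), out / "genus_tests.tsv")


def run_pipeline(
    fractions: str | Path,
    counts: str | Path,
    taxonomy: str | Path,
    samples: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    sep: str | None = None,
) -> QsipResults:
    """File-to-file convenience wrapper used by the command line."""
    model = NitrogenQsip.from_files(fractions, counts, taxonomy, samples, config=config, sep=sep)
    res = model.fit()
    res.to_directory(out_dir)
    return res
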