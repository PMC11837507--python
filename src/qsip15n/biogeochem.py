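"""Scalar soil-N biogeochemistry calculators.

Net nitrification and net immobilization rates from inorganic N pools
before and after an incubation, plant :sup:`15`\\ N recovery and uptake
rate, and fertilizer amendment unit conversions.
"""

from __future__ import annotations

from dataclasses import dataclass

N_MOLAR_MASS = 14.0067  # g/mol
CM2_PER_HA = 1e8
KG_PER_UG = 1e-9


@dataclass(frozen=True)
class InorganicNPools:
    """Extractable inorganic N pools at one time point.

    nh4, no3 in µg N per g dry soil; time in days since incubation start.
    """

    nh4: float
    no3: float
    time: float

    def __post_init__(self) -> None:
        if self.nh4 < 0 or self.no3 < 0:
            raise ValueError("inorganic N pools must be >= 0")

    @property
    def total(self) -> float:
        return self.nh4 + self.no3


def _delta_days(initial: InorganicNPools, final: InorganicNPools) -> float:
    dt = final.time - initial.time
    if dt <= 0:
        raise ValueError(f"final.time - initial.time must be > 0, got {dt}")
    return dt


def net_nitrification_rate(initial: InorganicNPools, final: InorganicNPools) -> float:
    """Net NO3- accumulation rate, µg N g^-1 day^-1 (negative = consumption)."""
    return (final.no3 - initial.no3) / _delta_days(initial, final)


def net_immobilization_rate(
    initial: InorganicNPools, final: InorganicNPools, n_added: float = 0.0
) -> float:
    """Net disappearance of total inorganic N, µg N g^-1 day^-1.

    The amendment ``n_added`` (µg N/g) joins the initial pool because
    incubations begin with the N addition; positive values mean net
    immobilization, negative net mineralization.
    """
    if n_added < 0:
        raise ValueError("n_added must be >= 0")
    return (initial.total + n_added - final.total) / _delta_days(initial, final)


def plant_15n_recovery(excess_15n_in_plant: float, added_15n: float) -> float:
    """Percent of the added 15N tracer recovered in plant biomass."""
    if added_15n <= 0:
        raise ValueError("added_15n must be > 0")
    return 100.0 * excess_15n_in_plant / added_15n


def uptake_rate(
    atom_pct_excess_sample: float,
    total_n: float,
    atom_pct_excess_reference: float,
    time: float,
) -> float:
    """Plant N uptake rate, (atom% excess x total N)/(reference atom% excess x days).

    ``atom_pct_excess_reference`` is the enrichment of the applied label
    (98 atom% for the tracer used here); ``total_n`` in g N; result in
    g N per day.
    """
    if atom_pct_excess_reference <= 0 or time <= 0:
        raise ValueError("reference enrichment and time must be > 0")
    return (atom_pct_excess_sample * total_n) / (atom_pct_excess_reference * time)


def amendment_units(
    n_conc: float, depth: float | None = None, bulk_density: float | None = None
) -> tuple[float, float | None]:
    """Convert a molar N amendment to mass-based and areal units.

    Parameters
    ----------
    n_conc : float
        Amendment in µmol N per g dry soil.
    depth : float, optional
        Incorporation depth in cm (needed for the areal rate).
    bulk_density : float, optional
        Soil bulk density in g/cm³ (needed for the areal rate).

    Returns
    -------
    (µg N per g soil, kg N per ha or None)
    """
    if n_conc < 0:
        raise ValueError("n_conc must be >= 0")
    ug_per_g = n_conc * N_MOLAR_MASS
    if depth is None or bulk_density is None:
        return ug_per_g, None
    if depth <= 0 or bulk_density <= 0:
        raise ValueError("depth and bulk_density must be > 0")
    kg_per_ha = ug_per_g * (CM2_PER_HA * depth * bulk_density) * KG_PER_UG
    return ug_per_g, kg_per_ha
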