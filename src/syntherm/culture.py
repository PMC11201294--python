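"""Batch-culture measurement model and unit plumbing.

Holds weekly measurements of VFA concentrations, headspace gas mole
fractions, total pressure, pH and temperature for sealed serum-bottle
cultures, and derives partial pressures, venting-corrected cumulative
methane, and free-ammonia speciation from them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .thermo import ChemicalState

logger = logging.getLogger(__name__)

#: Atmospheric pressure used to convert gauge readings, mbar.
ATMOSPHERIC_MBAR = 1013.25
#: Gas constant in J/(mol K) for ideal-gas headspace accounting.
R_J = 8.314462618

#: The eight short-chain VFA tracked by the HPLC assay, all in mM.
VFA_NAMES = (
    "acetate",
    "propionate",
    "butyrate",
    "isobutyrate",
    "valerate",
    "isovalerate",
    "caproate",
    "isocaproate",
)

GAS_NAMES = ("CH4", "CO2", "H2")

#: Ammonia dissociation pKa(T) = 0.09018 + 2729.92/T (Hansen et al. 1998).
NH3_PKA_A = 0.09018
NH3_PKA_B = 2729.92


class CultureError(ValueError):
    """Raised for invalid or inconsistent culture measurements."""


@dataclass
class Measurement:
    """One sampling event of a batch culture."""

    day: float
    vfa: dict[str, float] = field(default_factory=dict)  # mM
    gas_fraction: dict[str, float] = field(default_factory=dict)  # mole fraction
    total_pressure: float = 0.0  # mbar
    pressure_is_gauge: bool = True
    pH: float = 7.0
    temperature: float = 310.15  # K
    vented: bool = False
    post_vent_pressure: float | None = None  # mbar, same gauge convention

    def __post_init__(self) -> None:
        frac_sum = sum(self.gas_fraction.values())
        for g, x in self.gas_fraction.items():
            if not (0.0 <= x <= 1.0):
                raise CultureError(f"day {self.day}: mole fraction of {g} = {x} not in [0, 1]")
        if frac_sum > 1.0 + 1e-9:
            raise CultureError(f"day {self.day}: gas mole fractions sum to {frac_sum:.4f} > 1")
        if not (0.0 < self.pH < 14.0):
            raise CultureError(f"day {self.day}: pH {self.pH} out of (0, 14)")
        if self.total_pressure < 0 and not self.pressure_is_gauge:
            raise CultureError(f"day {self.day}: negative absolute pressure")
        if self.vented and self.post_vent_pressure is None:
            raise CultureError(f"day {self.day}: vented record lacks post-vent pressure")

    def absolute_pressure_mbar(self) -> float:
        return self.total_pressure + (ATMOSPHERIC_MBAR if self.pressure_is_gauge else 0.0)

    def post_vent_absolute_mbar(self) -> float | None:
        if self.post_vent_pressure is None:
            return None
        return self.post_vent_pressure + (ATMOSPHERIC_MBAR if self.pressure_is_gauge else 0.0)


@dataclass
class BatchTimeSeries:
    """Ordered measurements of one culture with its bottle geometry."""

    records: list[Measurement]
    culture_id: str = "culture"
    headspace_volume: float = 0.5  # L
    liquid_volume: float = 0.5  # L

    def __post_init__(self) -> None:
        if self.headspace_volume <= 0 or self.liquid_volume <= 0:
            raise CultureError("bottle volumes must be positive")
        days = [m.day for m in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise CultureError("measurement days must be strictly increasing")

    def days(self) -> list[float]:
        return [m.day for m in self.records]


@dataclass
class AmmoniaState:
    """Total ammonia nitrogen and its unionized NH3 fraction."""

    tan: float  # mol/L
    free_nh3: float  # mol/L
    fraction_nh3: float
    pH: float
    temperature: float


def partial_pressures(m: Measurement) -> dict[str, float]:
    """Species partial pressures in Pa: p_i = x_i * P_total(absolute)."""
    p_abs_pa = m.absolute_pressure_mbar() * 100.0
    return {g: x * p_abs_pa for g, x in m.gas_fraction.items()}


def headspace_moles(m: Measurement, headspace_volume_l: float) -> dict[str, float]:
    """Ideal-gas moles of each measured gas in the headspace, mmol."""
    pp = partial_pressures(m)
    v_m3 = headspace_volume_l / 1000.0
    return {g: 1000.0 * p * v_m3 / (R_J * m.temperature) for g, p in pp.items()}


def cumulative_methane(series: BatchTimeSeries) -> list[tuple[float, float]]:
    """Cumulative CH4 produced (mmol), correcting for venting events.

    Measurements on vented days reflect the pre-vent headspace; the moles
    removed by each vent (n_pre - n_post, with mole fractions unchanged
    by the release) are added back to every later timepoint.  Production
    is reported relative to the first record.
    """
    out: list[tuple[float, float]] = []
    removed_so_far = 0.0
    baseline: float | None = None
    v_m3 = series.headspace_volume / 1000.0
    for m in series.records:
        x_ch4 = m.gas_fraction.get("CH4", 0.0)
        n_now = 1000.0 * x_ch4 * m.absolute_pressure_mbar() * 100.0 * v_m3 / (R_J * m.temperature)
        if baseline is None:
            baseline = n_now
        out.append((m.day, n_now - baseline + removed_so_far))
        if m.vented:
            post = m.post_vent_absolute_mbar()
            if post is None:
                raise CultureError(f"day {m.day}: vented record lacks post-vent pressure")
            n_post = 1000.0 * x_ch4 * post * 100.0 * v_m3 / (R_J * m.temperature)
            removed_so_far += n_now - n_post
    return out


def free_ammonia(tan: float, pH: float, temperature: float) -> AmmoniaState:
    """Free NH3 from total ammonia nitrogen, pH and temperature.

    fraction = 1 / (1 + 10**(-pH) / Ka) with pKa = 0.09018 + 2729.92/T.
    """
    if tan < 0:
        raise CultureError("TAN must be non-negative")
    if temperature <= 0:
        raise CultureError("temperature must be positive (Kelvin)")
    pka = NH3_PKA_A + NH3_PKA_B / temperature
    fraction = 1.0 / (1.0 + 10.0 ** (-pH) / 10.0 ** (-pka))
    return AmmoniaState(
        tan=tan,
        free_nh3=tan * fraction,
        fraction_nh3=fraction,
        pH=pH,
        temperature=temperature,
    )


def to_chemical_state(m: Measurement) -> ChemicalState:
    """Build a thermodynamic state from one measurement (VFA mM -> mol/L)."""
    return ChemicalState(
        solute_concentrations={k: v / 1000.0 for k, v in m.vfa.items()},
        gas_partial_pressures=partial_pressures(m),
        pH=m.pH,
        temperature=m.temperature,
    )


# ---------------------------------------------------------------------------
# CSV dialect


CSV_COLUMNS = (
    ["day"]
    + [f"{a}_mM" for a in VFA_NAMES]
    + ["xCH4", "xCO2", "xH2", "pressure_mbar", "gauge", "pH", "temp_K", "vented",
       "post_vent_pressure_mbar"]
)


def read_batch_csv(
    path,
    culture_id: str = "culture",
    headspace_volume: float | None = None,
    liquid_volume: float | None = None,
) -> BatchTimeSeries:
    """Read the measurement-table dialect written by :func:`write_batch_csv`.

    Bottle volumes may be given as arguments or in ``# key = value``
    comment headers; missing VFA columns default to 0 with a warning.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    if headspace_volume is None:
        headspace_volume = float(meta.get("headspace_volume_L", 0.5))
    if liquid_volume is None:
        liquid_volume = float(meta.get("liquid_volume_L", 0.5))
    culture_id = meta.get("culture_id", culture_id)

    records = []
    for i, row in df.iterrows():
        vfa = {}
        for acid in VFA_NAMES:
            col = f"{acid}_mM"
            if col in df.columns:
                vfa[acid] = float(row[col])
            else:
                vfa[acid] = 0.0
        missing = [a for a in VFA_NAMES if f"{a}_mM" not in df.columns]
        if i == 0 and missing:
            logger.warning("missing VFA columns default to 0: %s", ", ".join(missing))
        post = row.get("post_vent_pressure_mbar")
        vented = bool(row.get("vented", False))
        try:
            records.append(
                Measurement(
                    day=float(row["day"]),
                    vfa=vfa,
                    gas_fraction={
                        "CH4": float(row.get("xCH4", 0.0)),
                        "CO2": float(row.get("xCO2", 0.0)),
                        "H2": float(row.get("xH2", 0.0)),
                    },
                    total_pressure=float(row["pressure_mbar"]),
                    pressure_is_gauge=bool(row.get("gauge", True)),
                    pH=float(row["pH"]),
                    temperature=float(row.get("temp_K", 310.15)),
                    vented=vented,
                    post_vent_pressure=None if pd.isna(post) else float(post),
                )
            )
        except CultureError as exc:
            raise CultureError(f"row {i + 1}: {exc}") from exc
    return BatchTimeSeries(
        records=records,
        culture_id=culture_id,
        headspace_volume=headspace_volume,
        liquid_volume=liquid_volume,
    )


def write_batch_csv(series: BatchTimeSeries, path, extra_header: Iterable[str] = ()) -> None:
    """Write the measurement table with volume metadata as comment headers."""
    rows = []
    for m in series.records:
        row = {"day": m.day}
        for acid in VFA_NAMES:
            row[f"{acid}_mM"] = m.vfa.get(acid, 0.0)
        row["xCH4"] = m.gas_fraction.get("CH4", 0.0)
        row["xCO2"] = m.gas_fraction.get("CO2", 0.0)
        row["xH2"] = m.gas_fraction.get("H2", 0.0)
        row["pressure_mbar"] = m.total_pressure
        row["gauge"] = m.pressure_is_gauge
        row["pH"] = m.pH
        row["temp_K"] = m.temperature
        row["vented"] = m.vented
        row["post_vent_pressure_mbar"] = (
            "" if m.post_vent_pressure is None else m.post_vent_pressure
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    with open(path, "w") as fh:
        for line in extra_header:
            fh.write(f"# {line}\n")
        fh.write(f"# culture_id = {series.culture_id}\n")
        fh.write(f"# headspace_volume_L = {series.headspace_volume}\n")
        fh.write(f"# liquid_volume_L = {series.liquid_volume}\n")
        df.to_csv(fh, index=False)
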