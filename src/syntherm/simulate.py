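"""Synthetic batch cultures and proteomes for end-to-end testing.

``simulate_batch`` emulates the measurement tables of a mesophilic,
high-ammonia propionate enrichment: a lag phase, a first propionate
degradation phase with stoichiometric (default 1:1) acetate
accumulation, a plateau during which the acetate-oxidizing community
consumes the accumulated acetate, and a second propionate degradation
phase with concurrent acetate consumption.  Kinetics are piecewise
linear — the shape and stoichiometry of the observed trajectories, not a
mechanistic growth model.  Headspace gases follow the syntrophic
stoichiometry (1 propionate -> 1 acetate + 3 H2 + 1 CO2; 1 acetate ->
2 CO2 + 4 H2; 4 H2 + 1 CO2 -> 1 CH4), so net 3/4 CH4 per propionate
oxidized and 1 CH4 per acetate oxidized, with venting events whenever
gauge pressure exceeds 1,000 mbar (reduced to ~100 mbar gauge).

``simulate_proteome`` plants metal-binding motifs (and NuoF neighbors
for bifurcating-A3 cases) into random background proteins and records
the ground truth for classifier tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .culture import ATMOSPHERIC_MBAR, R_J, BatchTimeSeries, Measurement
from .hydrogenase import AA_ALPHABET, GeneRecord, MotifRule, load_motif_rules

#: CH4 yield per mole of acid oxidized via hydrogenotrophic methanogenesis.
CH4_PER_PROPIONATE = 0.75  # 3 H2 / 4
CH4_PER_ACETATE = 1.0  # 4 H2 / 4
#: Net CO2 release per mole of acid oxidized (after methanogenesis).
CO2_PER_PROPIONATE = 0.25  # 1 produced - 3/4 consumed
CO2_PER_ACETATE = 1.0  # 2 produced - 1 consumed


class SimulationError(ValueError):
    pass


def _default_noise() -> dict[str, float]:
    return {
        "vfa_mM": 1.0,
        "xCH4": 0.005,
        "xCO2": 0.005,
        "xH2": 2.0e-6,
        "pressure_mbar": 5.0,
        "pH": 0.03,
    }


@dataclass
class BatchSimParams:
    """Study-condition parameters of the synthetic batch culture.

    Defaults mirror the 100 mM propionate regime: ~15 d lag, a first
    degradation phase of ~9 weeks, a ~6 week plateau, and a second
    degradation phase running to exhaustion, with H2 a few Pa above
    baseline while the acetate oxidizer is active.
    """

    initial_propionate: float = 100.0  # mM
    initial_acetate: float = 1.0  # mM
    lag_days: float = 15.0
    phase1_rate: float = 1.0  # mM/day propionate consumed
    phase1_days: float = 63.0
    plateau_days: float = 42.0
    phase2_rate: float = 0.8  # mM/day propionate consumed
    acetate_yield: float = 1.0  # mol acetate per mol propionate
    acetate_ox_rate: float = 1.2  # mM/day while SAOB-active
    acetate_min: float = 0.3  # mM residual the acetate oxidizer cannot deplete
    h2_baseline: float = 2.2  # Pa
    h2_pulse: float = 5.3  # Pa during the SAOB-active interval
    sampling_interval_days: float = 7.0
    duration_days: float | None = None  # None: run to propionate exhaustion
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    headspace_volume: float = 0.5  # L
    liquid_volume: float = 0.5  # L
    temperature: float = 310.15  # K
    initial_pco2: float = 26700.0  # Pa
    co2_to_headspace_fraction: float = 0.1  # rest absorbed by the bicarbonate buffer
    vent_threshold_mbar: float = 1000.0  # gauge
    post_vent_mbar: float = 100.0  # gauge
    pH_profile: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 7.25), (200.0, 7.5)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("phase1_rate", "phase2_rate", "acetate_ox_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not (0.0 <= self.acetate_yield <= 1.0):
            raise SimulationError("acetate_yield must be in [0, 1]")
        if self.sampling_interval_days <= 0:
            raise SimulationError("sampling interval must be positive")
        if self.headspace_volume <= 0 or self.liquid_volume <= 0:
            raise SimulationError("volumes must be positive")

    def phase_schedule(self) -> dict[str, tuple[float, float]]:
        """True phase boundaries (day intervals) implied by the parameters."""
        t1 = self.lag_days
        t2 = t1 + self.phase1_days
        t3 = t2 + self.plateau_days
        remaining = self.initial_propionate - self.phase1_rate * self.phase1_days
        remaining = max(remaining, 0.0)
        t4 = t3 + (remaining / self.phase2_rate if self.phase2_rate > 0 else 0.0)
        return {
            "lag": (0.0, t1),
            "degradation-1": (t1, t2),
            "plateau": (t2, t3),
            "degradation-2": (t3, t4),
        }

    def pH_at(self, day: float) -> float:
        anchors = sorted(self.pH_profile)
        xs = [a for a, _ in anchors]
        ys = [b for _, b in anchors]
        return float(np.interp(day, xs, ys))


def simulate_batch(params: BatchSimParams) -> BatchTimeSeries:
    """Noisy measurement table for the parameterized trajectory."""
    series, _ = simulate_batch_with_truth(params)
    return series


def simulate_batch_with_truth(
    params: BatchSimParams,
) -> tuple[BatchTimeSeries, pd.DataFrame]:
    """Simulate and also return the noiseless bookkeeping table.

    The truth table carries, per sampled day: true VFA concentrations,
    cumulative CH4 and CO2 produced (mmol), the dissolved-CO2 pool,
    headspace composition and pressure, venting flags and the phase
    label of the generator schedule.
    """
    p = params
    sched = p.phase_schedule()
    end_of_run = sched["degradation-2"][1]
    duration = p.duration_days if p.duration_days is not None else end_of_run
    n_days = int(math.ceil(duration))

    # headspace initialized at atmospheric pressure with the target pCO2,
    # remainder N2; moles in mmol
    v_m3 = p.headspace_volume / 1000.0
    rt = R_J * p.temperature
    n_total0 = 1000.0 * ATMOSPHERIC_MBAR * 100.0 * v_m3 / rt
    n_co2 = 1000.0 * p.initial_pco2 * v_m3 / rt
    n_n2 = n_total0 - n_co2
    n_ch4 = 0.0

    pro = p.initial_propionate  # mM, true
    ace = p.initial_acetate
    ch4_cum = 0.0  # mmol produced
    co2_cum = 0.0  # mmol produced (headspace + dissolved)
    co2_dissolved = 0.0

    sample_days = [
        float(d) for d in np.arange(0.0, n_days + 1e-9, p.sampling_interval_days)
    ]
    sample_set = set(sample_days)

    ss = np.random.SeedSequence(p.seed)
    channels = ("vfa_mM", "xCH4", "xCO2", "xH2", "pressure_mbar", "pH")
    rngs = {
        ch: np.random.default_rng(child)
        for ch, child in zip(channels, ss.spawn(len(channels)))
    }

    truth_rows = []
    records = []

    def phase_of(day: float) -> str:
        for name, (a, b) in sched.items():
            if a <= day < b:
                return name
        return "degradation-2" if day < end_of_run + 1e-9 else "post"

    def record_sample(day: float) -> None:
        n_total = n_ch4 + n_co2 + n_n2
        pressure_pa = n_total / 1000.0 * rt / v_m3
        pressure_mbar_abs = pressure_pa / 100.0
        gauge = pressure_mbar_abs - ATMOSPHERIC_MBAR

        phase = phase_of(day)
        saob_active = phase in ("plateau", "degradation-2")
        ph2 = p.h2_pulse if saob_active else p.h2_baseline
        x_ch4 = n_ch4 / n_total
        x_co2 = n_co2 / n_total
        x_h2 = ph2 / pressure_pa

        vented = gauge > p.vent_threshold_mbar
        post_gauge = p.post_vent_mbar if vented else None

        truth_rows.append(
            {
                "day": day,
                "phase": phase,
                "propionate_mM": pro,
                "acetate_mM": ace,
                "ch4_cum_mmol": ch4_cum,
                "co2_cum_mmol": co2_cum,
                "co2_dissolved_mmol": co2_dissolved,
                "ch4_headspace_mmol": n_ch4,
                "co2_headspace_mmol": n_co2,
                "pressure_gauge_mbar": gauge,
                "pH2_Pa": ph2,
                "xCH4": x_ch4,
                "xCO2": x_co2,
                "pH": p.pH_at(day),
                "vented": vented,
            }
        )

        def noisy(value, channel, lo=0.0, hi=None):
            sd = p.noise_sd.get(channel, 0.0)
            v = value + (rngs[channel].normal(0.0, sd) if sd > 0 else 0.0)
            if lo is not None:
                v = max(v, lo)
            if hi is not None:
                v = min(v, hi)
            return v

        vfa = {name: 0.0 for name in
               ("butyrate", "isobutyrate", "valerate", "isovalerate",
                "caproate", "isocaproate")}
        vfa["acetate"] = noisy(ace, "vfa_mM")
        vfa["propionate"] = noisy(pro, "vfa_mM")
        records.append(
            Measurement(
                day=day,
                vfa=vfa,
                gas_fraction={
                    "CH4": noisy(x_ch4, "xCH4", hi=1.0),
                    "CO2": noisy(x_co2, "xCO2", hi=1.0),
                    "H2": noisy(x_h2, "xH2", hi=1.0),
                },
                total_pressure=noisy(gauge, "pressure_mbar", lo=None),
                pressure_is_gauge=True,
                pH=noisy(p.pH_at(day), "pH", lo=1e-6, hi=14.0 - 1e-6),
                temperature=p.temperature,
                vented=vented,
                post_vent_pressure=post_gauge,
            )
        )

    def apply_vent() -> None:
        nonlocal n_ch4, n_co2, n_n2
        n_total = n_ch4 + n_co2 + n_n2
        pressure_pa = n_total / 1000.0 * rt / v_m3
        gauge = pressure_pa / 100.0 - ATMOSPHERIC_MBAR
        if gauge > p.vent_threshold_mbar:
            target_pa = (ATMOSPHERIC_MBAR + p.post_vent_mbar) * 100.0
            keep = target_pa / pressure_pa
            n_ch4 *= keep
            n_co2 *= keep
            n_n2 *= keep

    liquid_mmol_per_mM = p.liquid_volume  # mmol = mM * L

    for day in range(0, n_days + 1):
        fday = float(day)
        if fday in sample_set:
            record_sample(fday)
            apply_vent()
        # one-day Euler step of the piecewise-linear kinetics
        phase = phase_of(fday)
        d_pro = 0.0
        if phase == "degradation-1":
            d_pro = min(p.phase1_rate, pro)
        elif phase in ("degradation-2",):
            d_pro = min(p.phase2_rate, pro)
        saob_active = phase in ("plateau", "degradation-2")
        available = max(ace + p.acetate_yield * d_pro - p.acetate_min, 0.0)
        d_ace_ox = min(p.acetate_ox_rate, available) if saob_active else 0.0

        pro -= d_pro
        ace += p.acetate_yield * d_pro - d_ace_ox

        ch4_new = (
            CH4_PER_PROPIONATE * d_pro + CH4_PER_ACETATE * d_ace_ox
        ) * liquid_mmol_per_mM
        co2_new = (
            CO2_PER_PROPIONATE * d_pro + CO2_PER_ACETATE * d_ace_ox
        ) * liquid_mmol_per_mM
        ch4_cum += ch4_new
        co2_cum += co2_new
        n_ch4 += ch4_new
        n_co2 += p.co2_to_headspace_fraction * co2_new
        co2_dissolved += (1.0 - p.co2_to_headspace_fraction) * co2_new

    series = BatchTimeSeries(
        records=records,
        culture_id=f"synthetic-P{int(round(p.initial_propionate))}-seed{p.seed}",
        headspace_volume=p.headspace_volume,
        liquid_volume=p.liquid_volume,
    )
    return series, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Proteome generator


def _materialize(pattern: str, rng: np.random.Generator) -> str:
    """Draw a concrete sequence matching one of the rule-file regexes.

    Supports the restricted grammar the bundled rules use: literal
    residues, character classes, and nothing else.
    """
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            spec = pattern[i + 1 : j]
            choices = _expand_class(spec)
            out.append(choices[rng.integers(len(choices))])
            i = j + 1
        elif ch in AA_ALPHABET:
            out.append(ch)
            i += 1
        else:
            raise SimulationError(f"cannot materialize regex construct {ch!r} in {pattern!r}")
    return "".join(out)


def _expand_class(spec: str) -> str:
    chars = []
    i = 0
    while i < len(spec):
        if i + 2 < len(spec) and spec[i + 1] == "-":
            lo, hi = spec[i], spec[i + 2]
            chars.extend(chr(c) for c in range(ord(lo), ord(hi) + 1))
            i += 3
        else:
            chars.append(spec[i])
            i += 1
    return "".join(c for c in chars if c in AA_ALPHABET)


def _background_sequence(
    rng: np.random.Generator, compiled, length: int | None = None
) -> str:
    """Random protein with no motif hits (rejection-sampled)."""
    alphabet = np.array(list(AA_ALPHABET))
    while True:
        n = int(rng.integers(300, 601)) if length is None else length
        seq = "".join(rng.choice(alphabet, size=n))
        if not any(rx.search(seq) for _, rx in compiled):
            return seq


def simulate_proteome(
    n_genes: int,
    planted: list[tuple[str, int]],
    seed: int = 0,
    rules: list[MotifRule] | None = None,
    contig_length: int = 40,
    negative_control_prob: float = 0.5,
) -> tuple[list[GeneRecord], pd.DataFrame, pd.DataFrame]:
    """Random proteome with hydrogenases planted at recorded positions.

    ``planted`` maps HydDB-style group labels (e.g. "FeFe A3", "FeFe A",
    "NiFe 1a") to counts.  FeFe groups receive an H-cluster L1 motif,
    NiFe groups a nickel-binding L1 motif.  Each planted "FeFe A3" gets
    a NuoF-labeled neighbor at ordinal distance 1..5 (inclusive
    boundary); non-A3 FeFe plants get, with probability
    ``negative_control_prob``, a NuoF at distance exactly 6 as a
    negative control.  Background sequences are rejection-sampled
    against the rule file, so noiseless fixtures contain no spurious
    motifs.  Returns (records, gene-order table, truth table).
    """
    if any(count < 0 for _, count in planted):
        raise SimulationError("planted counts must be >= 0")
    rules = load_motif_rules() if rules is None else rules
    compiled = [(r, r.compiled()) for r in rules]
    by_class: dict[str, list[MotifRule]] = {}
    for r in rules:
        by_class.setdefault(r.metal_class, []).append(r)
    for group, count in planted:
        metal = group.split()[0]
        if count > 0 and metal not in by_class:
            raise SimulationError(f"no rules for metal class of group {group!r}")

    rng = np.random.default_rng(seed)
    plant_list: list[str] = []
    for group, count in planted:
        plant_list.extend([group] * count)
    rng.shuffle(plant_list)

    n_planted = len(plant_list)
    # planted genes (plus NuoF partners) occupy spaced slots so proximity
    # evidence never leaks between plants: one plant per 15-ordinal block
    # (worst-case gap between a plant and a neighboring block's NuoF is 7)
    slots_per_contig = max(1, contig_length // 15)
    n_contigs_planted = int(math.ceil(n_planted / slots_per_contig)) if n_planted else 0

    records: list[GeneRecord] = []
    truth_rows = []
    gene_counter = 0

    def new_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"gene_{gene_counter:05d}"

    def background_record(contig: str, ordinal: int, product="hypothetical protein"):
        return GeneRecord(
            gene_id=new_gene_id(),
            contig_id=contig,
            ordinal=ordinal,
            product_label=product,
            protein_sequence=_background_sequence(rng, compiled),
        )

    plant_iter = iter(plant_list)
    contigs_needed = max(
        n_contigs_planted, int(math.ceil(n_genes / contig_length))
    )
    planted_remaining = n_planted
    for ci in range(contigs_needed):
        contig = f"contig_{ci + 1:03d}"
        special: dict[int, tuple[str, str]] = {}  # ordinal -> (kind, payload)
        for si in range(slots_per_contig):
            if planted_remaining == 0:
                break
            group = next(plant_iter)
            planted_remaining -= 1
            base = si * 15 + 3 + int(rng.integers(0, 3))  # jittered block anchor
            metal = group.split()[0]
            rule = by_class[metal][0]  # L1 motif of the class
            special[base] = ("hyd", f"{group}|{rule.name}")
            if group == "FeFe A3":
                d = int(rng.integers(1, 6))  # inclusive 1..5
                special[base + d] = ("nuof", "")
                nuof_d = d
            elif metal == "FeFe" and rng.random() < negative_control_prob:
                special[base + 6] = ("nuof", "")  # distance-6 negative control
                nuof_d = 6
            else:
                nuof_d = None
            truth_rows.append(
                {
                    "group": group,
                    "metal_class": metal,
                    "rule": rule.name,
                    "contig": contig,
                    "ordinal": base,
                    "nuof_distance": nuof_d,
                }
            )

        for ordinal in range(contig_length):
            kind, payload = special.get(ordinal, ("bg", ""))
            if kind == "hyd":
                group, rule_name = payload.split("|")
                rule = next(r for r in rules if r.name == rule_name)
                motif = _materialize(rule.pattern, rng)
                bg = _background_sequence(rng, compiled)
                pos = int(rng.integers(50, len(bg) - len(motif) - 50))
                seq = bg[:pos] + motif + bg[pos + len(motif):]
                # motif splice may create new flanking matches; resample
                while sum(
                    1 for _, rx in compiled for _ in rx.finditer(seq)
                ) != 1 or not rule.compiled().search(seq):
                    bg = _background_sequence(rng, compiled)
                    pos = int(rng.integers(50, len(bg) - len(motif) - 50))
                    seq = bg[:pos] + motif + bg[pos + len(motif):]
                rec = GeneRecord(
                    gene_id=new_gene_id(),
                    contig_id=contig,
                    ordinal=ordinal,
                    product_label="hydrogenase-like protein",
                    protein_sequence=seq,
                )
                for row in truth_rows:
                    if row["contig"] == contig and row["ordinal"] == ordinal:
                        row["gene_id"] = rec.gene_id
                        row["motif_start"] = pos
            elif kind == "nuof":
                rec = GeneRecord(
                    gene_id=new_gene_id(),
                    contig_id=contig,
                    ordinal=ordinal,
                    product_label="NADH-quinone oxidoreductase subunit NuoF",
                    protein_sequence=_background_sequence(rng, compiled),
                )
            else:
                rec = background_record(contig, ordinal)
            records.append(rec)

    gene_order = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "contig": [r.contig_id for r in records],
            "ordinal": [r.ordinal for r in records],
            "product": [r.product_label for r in records],
        }
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "group", "metal_class", "rule", "contig", "ordinal",
                 "motif_start", "nuof_distance"],
    )
    return records, gene_order, truth


def write_proteome_fasta(records: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id} {r.product_label}\n")
            for i in range(0, len(r.protein_sequence), 60):
                fh.write(r.protein_sequence[i : i + 60] + "\n")


def params_to_dict(params: BatchSimParams) -> dict:
    return asdict(params)
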