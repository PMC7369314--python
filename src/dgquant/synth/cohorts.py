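"""Synthetic animal cohorts with the study's 2-sex x 5-time-point design.

The generator draws per-animal endpoints around group-level truths supplied
by a :class:`CohortDesign`:

* per (sex, region, time) true BrdU-ir cell density, with per-animal
  log-normal scatter (densities are positive and right-skewed; log-normal
  noise never produces a negative animal at small n);
* per (sex, region, time) true co-expression probabilities for NeuN, DCX and
  Sox2, realized per animal as a binomial draw over the 50-cell sample;
* a DCX morphology-type mixture (A/B/C) realized as a multinomial over the
  DCX-positive subsample;
* hormone levels — serum estradiol for females (lavage cytology at the 2-h
  and 24-h time points, where cycle stage was determined that way) and serum
  testosterone for males.

The default calibration (``default_design``) is illustrative: it encodes the
qualitative structure of the study system — a male density peak at 1 week
followed by ~50% attrition by 2 weeks, a flat female trajectory, faster male
NeuN maturation with both sexes near 90% NeuN at 3 weeks, more dorsal stem
cells in males, and non-proestrous females in the week groups — with round
numbers, not measured group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dgquant.phenotyping import (
    HormonePanel,
    TARGET_SAMPLE_SIZE,
    classify_proestrus_estradiol,
    classify_proestrus_lavage,
)

__all__ = [
    "SEXES",
    "TIME_POINTS",
    "REGIONS",
    "CohortDesign",
    "AnimalRecord",
    "default_design",
    "generate_cohort",
    "cohort_to_frame",
]

SEXES = ("male", "female")
TIME_POINTS = ("2h", "24h", "1w", "2w", "3w")
REGIONS = ("dorsal", "ventral")

GroupKey = tuple[str, str, str]  # (sex, region, time)


@dataclass
class CohortDesign:
    """Group-level truth for a simulated cohort.

    ``brdu_density``, ``coexpression`` and ``dcx_type_mix`` are keyed by
    (sex, region, time); ``ki67_density`` and ``sox2_density`` by
    (sex, region) — proliferation and stem-cell endpoints were measured once
    per animal, not per time point.  ``density_cv`` is the coefficient of
    variation of the per-animal log-normal scatter.
    """

    n_per_group: int
    brdu_density: dict[GroupKey, float]
    coexpression: dict[GroupKey, dict[str, float]]  # marker -> p in [0,1]
    dcx_type_mix: dict[GroupKey, tuple[float, float, float]]
    ki67_density: dict[tuple[str, str], float]
    sox2_density: dict[tuple[str, str], float]
    estradiol_mean_pg_ml: float = 14.41
    estradiol_cv: float = 0.30
    testosterone_mean_ng_ml: float = 1.07
    testosterone_cv: float = 0.80
    proestrus_fraction_acute: float = 0.10  # 2-h/24-h groups, via lavage
    density_cv: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for key, dens in self.brdu_density.items():
            self._check_key(key)
            if dens < 0:
                raise ValueError(f"negative density for group {key}")
        for key, probs in self.coexpression.items():
            self._check_key(key)
            for marker, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{marker} probability {p} outside [0,1] for {key}")
        for key, mix in self.dcx_type_mix.items():
            self._check_key(key)
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"DCX type mixture for {key} must sum to 1")
            if any(p < 0 for p in mix):
                raise ValueError(f"negative mixture weight for {key}")

    @staticmethod
    def _check_key(key: GroupKey) -> None:
        sex, region, time = key
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}; allowed: {SEXES}")
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; allowed: {REGIONS}")
        if time not in TIME_POINTS:
            raise ValueError(f"unknown time point {time!r}; allowed: {TIME_POINTS}")


@dataclass
class AnimalRecord:
    """One simulated animal: densities and phenotypes per region, hormones."""

    animal_id: str
    sex: str
    time_point: str
    # per-region dicts keyed "dorsal"/"ventral"
    brdu_density: dict[str, float]
    ki67_density: dict[str, float]
    sox2_density: dict[str, float]
    pct_neun: dict[str, float]
    pct_dcx: dict[str, float]
    pct_sox2: dict[str, float]
    brdu_dcx_density: dict[str, float]
    brdu_sox2_density: dict[str, float]
    dcx_type_mix: dict[str, tuple[float, float, float]]
    hormones: HormonePanel
    proestrus: bool


# ---------------------------------------------------------------------------
# default calibration


def _trajectories() -> dict[GroupKey, float]:
    """Illustrative BrdU-ir density truths (cells/mm^3).

    Males rise to a 1-week peak at twice their 2-week level (so the designed
    1w -> 2w attrition is -50%); females are flat across time.  Ventral runs
    at 80% of dorsal.
    """
    male_dorsal = {"2h": 9000.0, "24h": 10000.0, "1w": 20000.0, "2w": 10000.0, "3w": 8000.0}
    female_dorsal = {t: 7000.0 for t in TIME_POINTS}
    out: dict[GroupKey, float] = {}
    for t in TIME_POINTS:
        out[("male", "dorsal", t)] = male_dorsal[t]
        out[("male", "ventral", t)] = 0.8 * male_dorsal[t]
        out[("female", "dorsal", t)] = female_dorsal[t]
        out[("female", "ventral", t)] = 0.8 * female_dorsal[t]
    return out


def _coexpression() -> dict[GroupKey, dict[str, float]]:
    """Illustrative marker probabilities.

    NeuN rises with maturation and rises faster in males (male lead at 2w,
    both sexes ~0.9 by 3w); DCX peaks around 1w and falls by 3w, with a
    female-only jump from 2h to 24h; Sox2 starts near 1 and decays.
    """
    neun = {
        "male": {"2h": 0.0, "24h": 0.0, "1w": 0.12, "2w": 0.70, "3w": 0.90},
        "female": {"2h": 0.0, "24h": 0.0, "1w": 0.12, "2w": 0.30, "3w": 0.90},
    }
    dcx = {
        "male": {"2h": 0.70, "24h": 0.70, "1w": 0.85, "2w": 0.75, "3w": 0.35},
        "female": {"2h": 0.35, "24h": 0.75, "1w": 0.85, "2w": 0.75, "3w": 0.35},
    }
    sox2 = {"2h": 0.95, "24h": 0.85, "1w": 0.30, "2w": 0.10, "3w": 0.05}
    out: dict[GroupKey, dict[str, float]] = {}
    for sex in SEXES:
        for region in REGIONS:
            for t in TIME_POINTS:
                out[(sex, region, t)] = {
                    "NeuN": neun[sex][t],
                    "DCX": dcx[sex][t],
                    "Sox2": sox2[t],
                }
    return out


def _dcx_mixes() -> dict[GroupKey, tuple[float, float, float]]:
    """Illustrative DCX A/B/C stage mixtures; males lead in type C at 2w."""
    base = {
        "2h": (0.80, 0.15, 0.05),
        "24h": (0.70, 0.25, 0.05),
        "1w": (0.40, 0.45, 0.15),
        "3w": (0.15, 0.45, 0.40),
    }
    two_w = {"male": (0.20, 0.45, 0.35), "female": (0.25, 0.55, 0.20)}
    out: dict[GroupKey, tuple[float, float, float]] = {}
    for sex in SEXES:
        for region in REGIONS:
            for t in TIME_POINTS:
                out[(sex, region, t)] = two_w[sex] if t == "2w" else base[t]
    return out


def default_design(n_per_group: int = 4, seed: int = 0) -> CohortDesign:
    """The default calibrated design.

    ``n_per_group`` defaults to 4, mirroring a 22-animals-per-sex cohort
    split over five perfusion time points; raise it for recovery tests.
    """
    design = CohortDesign(
        n_per_group=n_per_group,
        brdu_density=_trajectories(),
        coexpression=_coexpression(),
        dcx_type_mix=_dcx_mixes(),
        # males lead dorsally for stem cells; females show a ventral > dorsal
        # gradient; males proliferate more throughout
        ki67_density={
            ("male", "dorsal"): 4000.0,
            ("male", "ventral"): 3800.0,
            ("female", "dorsal"): 2500.0,
            ("female", "ventral"): 2400.0,
        },
        sox2_density={
            ("male", "dorsal"): 250000.0,
            ("male", "ventral"): 255000.0,
            ("female", "dorsal"): 175000.0,
            ("female", "ventral"): 260000.0,
        },
        seed=seed,
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# generation


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal draws with the requested arithmetic mean and CV."""
    if mean == 0:
        return np.zeros(size) if size else 0.0
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_cohort(design: CohortDesign) -> list[AnimalRecord]:
    """Draw one cohort; identical design (incl. seed) yields identical animals."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    records: list[AnimalRecord] = []
    counter = 0
    for sex in SEXES:
        for t in TIME_POINTS:
            for _ in range(design.n_per_group):
                counter += 1
                animal_id = f"{sex[0]}{t}-{counter:03d}"
                brdu, neun, dcx, sox2, bdcx, bsox2, mixes = {}, {}, {}, {}, {}, {}, {}
                ki67, sox2_dens = {}, {}
                for region in REGIONS:
                    key = (sex, region, t)
                    if key not in design.brdu_density:
                        raise ValueError(f"design has no BrdU density for group {key}")
                    d = _lognormal(rng, design.brdu_density[key], design.density_cv)
                    probs = design.coexpression[key]
                    n = TARGET_SAMPLE_SIZE
                    k_neun = rng.binomial(n, probs["NeuN"])
                    k_dcx = rng.binomial(n, probs["DCX"])
                    k_sox2 = rng.binomial(n, probs["Sox2"])
                    brdu[region] = float(d)
                    neun[region] = 100.0 * k_neun / n
                    dcx[region] = 100.0 * k_dcx / n
                    sox2[region] = 100.0 * k_sox2 / n
                    bdcx[region] = float(d) * k_dcx / n
                    bsox2[region] = float(d) * k_sox2 / n
                    n_dcx = max(int(k_dcx), 1)
                    mix_counts = rng.multinomial(n_dcx, design.dcx_type_mix[key])
                    mixes[region] = tuple(mix_counts / n_dcx)
                    ki67[region] = float(
                        _lognormal(rng, design.ki67_density[(sex, region)], design.density_cv)
                    )
                    sox2_dens[region] = float(
                        _lognormal(rng, design.sox2_density[(sex, region)], design.density_cv)
                    )
                if sex == "female":
                    if t in ("2h", "24h"):
                        # cycle stage from lavage cytology in the acute groups
                        if rng.uniform() < design.proestrus_fraction_acute:
                            frac = rng.uniform(0.70, 0.95)
                        else:
                            frac = rng.uniform(0.05, 0.55)
                        panel = HormonePanel(lavage_nucleated_fraction=float(frac))
                        proestrus = classify_proestrus_lavage(frac)
                    else:
                        e2 = float(
                            _lognormal(rng, design.estradiol_mean_pg_ml, design.estradiol_cv)
                        )
                        panel = HormonePanel(estradiol_pg_ml=e2)
                        proestrus = classify_proestrus_estradiol(e2)
                else:
                    testo = float(
                        _lognormal(rng, design.testosterone_mean_ng_ml, design.testosterone_cv)
                    )
                    panel = HormonePanel(testosterone_ng_ml=testo)
                    proestrus = False
                records.append(
                    AnimalRecord(
                        animal_id=animal_id,
                        sex=sex,
                        time_point=t,
                        brdu_density=brdu,
                        ki67_density=ki67,
                        sox2_density=sox2_dens,
                        pct_neun=neun,
                        pct_dcx=dcx,
                        pct_sox2=sox2,
                        brdu_dcx_density=bdcx,
                        brdu_sox2_density=bsox2,
                        dcx_type_mix=mixes,
                        hormones=panel,
                        proestrus=proestrus,
                    )
                )
    return records


def cohort_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Tidy long-over-region frame: one row per animal x region.

    Columns: animal_id, sex, time_point, region, the density and percentage
    endpoints, the DCX type fractions, hormone fields, and proestrus flag.
    """
    rows = []
    for r in records:
        for region in REGIONS:
            pa, pb, pc = r.dcx_type_mix[region]
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "sex": r.sex,
                    "time_point": r.time_point,
                    "region": region,
                    "brdu_density": r.brdu_density[region],
                    "ki67_density": r.ki67_density[region],
                    "sox2_density": r.sox2_density[region],
                    "brdu_dcx_density": r.brdu_dcx_density[region],
                    "brdu_sox2_density": r.brdu_sox2_density[region],
                    "pct_neun": r.pct_neun[region],
                    "pct_dcx": r.pct_dcx[region],
                    "pct_sox2": r.pct_sox2[region],
                    "pct_dcx_type_a": 100.0 * pa,
                    "pct_dcx_type_b": 100.0 * pb,
                    "pct_dcx_type_c": 100.0 * pc,
                    "estradiol_pg_ml": r.hormones.estradiol_pg_ml,
                    "testosterone_ng_ml": r.hormones.testosterone_ng_ml,
                    "lavage_nucleated_fraction": r.hormones.lavage_nucleated_fraction,
                    "proestrus": r.proestrus,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(records: list[AnimalRecord], path: str | Path) -> pd.DataFrame:
    """Write the tidy cohort table as CSV; return the frame."""
    df = cohort_to_frame(records)
    df.to_csv(path, index=False)
    return df
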