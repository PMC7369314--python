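"""Co-expression estimation, double-label densities, and classification rules.

Marker co-expression (e.g., the fraction of BrdU-birthdated cells that express
NeuN, DCX, or Sox2) is estimated by sampling a fixed number of labeled cells
per animal — 50 by design — and scoring each for the second marker.  Samples
that fall short of the 50-cell target (animals with few labeled cells) are
still estimated but flagged.

DCX-expressing immature neurons are staged by dendritic morphology:

* type A, proliferative — no processes, or short plump ones;
* type B, intermediate — medium-length processes, or an apical dendrite
  reaching the molecular layer without branching there;
* type C, postmitotic — an apical dendrite with at least one branch in the
  molecular layer.

Proestrus is classified either from serum estradiol (>= 50 pg/ml) or from
vaginal lavage cytology (>= 70% nucleated epithelial cells; the published
rule does not state whether exactly 70% qualifies — here it does).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PROESTRUS_ESTRADIOL_PG_ML",
    "PROESTRUS_LAVAGE_FRACTION",
    "TARGET_SAMPLE_SIZE",
    "CellSample",
    "DcxMorphology",
    "ProcessClass",
    "HormonePanel",
    "coexpression_pct",
    "double_label_density",
    "classify_dcx_morphology",
    "classify_proestrus_estradiol",
    "classify_proestrus_lavage",
    "sample_cells",
    "read_sample_table",
]

PROESTRUS_ESTRADIOL_PG_ML = 50.0
PROESTRUS_LAVAGE_FRACTION = 0.70
TARGET_SAMPLE_SIZE = 50


@dataclass(frozen=True)
class CellSample:
    """A per-animal sample of labeled cells scored for a second marker."""

    n_sampled: int
    n_colabeled: int
    marker: str = "NeuN"

    def __post_init__(self) -> None:
        if self.n_sampled < 1:
            raise ValueError("n_sampled must be >= 1")
        if not 0 <= self.n_colabeled <= self.n_sampled:
            raise ValueError(
                f"n_colabeled={self.n_colabeled} outside [0, n_sampled={self.n_sampled}]"
            )

    @property
    def under_target(self) -> bool:
        """True when fewer than the 50-cell target could be sampled."""
        return self.n_sampled < TARGET_SAMPLE_SIZE


class ProcessClass(str, Enum):
    NONE_OR_SHORT_PLUMP = "none_or_short_plump"
    MEDIUM_OR_APICAL_TO_ML = "medium_or_apical_to_ML"
    BRANCHED_IN_ML = "branched_in_ML"


@dataclass(frozen=True)
class DcxMorphology:
    """Symbolic dendrite descriptor of one DCX-expressing cell.

    Typing operates on these descriptors, not on pixels: the published staging
    was visual, and automated neurite tracing is out of scope.
    """

    process_class: ProcessClass
    reaches_molecular_layer: bool = False
    branches_in_molecular_layer: bool = False

    def __post_init__(self) -> None:
        if self.branches_in_molecular_layer and not self.reaches_molecular_layer:
            raise ValueError(
                "a dendrite cannot branch in the molecular layer without reaching it"
            )


@dataclass(frozen=True)
class HormonePanel:
    """Serum hormone levels and/or lavage cytology for one animal."""

    estradiol_pg_ml: float | None = None
    testosterone_ng_ml: float | None = None
    lavage_nucleated_fraction: float | None = None

    def __post_init__(self) -> None:
        if (
            self.estradiol_pg_ml is None
            and self.testosterone_ng_ml is None
            and self.lavage_nucleated_fraction is None
        ):
            raise ValueError("at least one hormone/cytology field must be present")


def coexpression_pct(sample: CellSample) -> float:
    """Percentage of sampled cells co-expressing the second marker, in [0, 100]."""
    return 100.0 * sample.n_colabeled / sample.n_sampled


def double_label_density(brdu_density: float, pct: float) -> float:
    """Density of double-labeled cells: labeled density x co-expression fraction."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"pct={pct} outside [0, 100]")
    if brdu_density < 0:
        raise ValueError("density must be non-negative")
    return brdu_density * pct / 100.0


def classify_dcx_morphology(m: DcxMorphology) -> str:
    """Stage a DCX cell as ``type_A``, ``type_B``, or ``type_C``.

    Type C takes precedence (a branch in the molecular layer), then type B
    (medium processes or an apical dendrite reaching the molecular layer),
    else type A.  Total and deterministic over all valid descriptors.
    """
    if m.branches_in_molecular_layer:
        return "type_C"
    if (
        m.process_class is not ProcessClass.NONE_OR_SHORT_PLUMP
        or m.reaches_molecular_layer
    ):
        return "type_B"
    return "type_A"


def classify_proestrus_estradiol(e2_pg_ml: float) -> bool:
    """Proestrus iff serum estradiol >= 50 pg/ml (inclusive)."""
    if e2_pg_ml < 0:
        raise ValueError("estradiol concentration must be non-negative")
    return e2_pg_ml >= PROESTRUS_ESTRADIOL_PG_ML


def classify_proestrus_lavage(nucleated_fraction: float) -> bool:
    """Proestrus iff >= 70% of lavage cells are nucleated epithelial cells."""
    if not 0.0 <= nucleated_fraction <= 1.0:
        raise ValueError("nucleated_fraction must lie in [0, 1]")
    return nucleated_fraction >= PROESTRUS_LAVAGE_FRACTION


def sample_cells(
    n_available: int,
    is_colabeled: np.ndarray | list[bool],
    marker: str,
    seed: int = 0,
) -> CellSample:
    """Draw the co-expression sample for one animal.

    Samples ``min(50, n_available)`` cells uniformly without replacement from
    the detected labeled cells; when fewer than 50 exist, all are used and the
    resulting :class:`CellSample` is flagged ``under_target``.
    """
    flags = np.asarray(is_colabeled, dtype=bool)
    if flags.size != n_available:
        raise ValueError("is_colabeled must have one entry per available cell")
    if n_available < 1:
        raise ValueError("need at least one labeled cell to sample")
    rng = np.random.default_rng(seed)
    n_take = min(TARGET_SAMPLE_SIZE, n_available)
    chosen = rng.choice(n_available, size=n_take, replace=False)
    return CellSample(
        n_sampled=n_take, n_colabeled=int(flags[chosen].sum()), marker=marker
    )


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a per-animal sample CSV and append the estimated percentages.

    Expects columns ``animal_id, marker, n_sampled, n_colabeled``; returns the
    frame with ``pct`` and ``under_target`` columns added.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "marker", "n_sampled", "n_colabeled"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table is missing columns: {sorted(missing)}")
    samples = [
        CellSample(int(r.n_sampled), int(r.n_colabeled), str(r.marker))
        for r in df.itertuples()
    ]
    df = df.assign(
        pct=[coexpression_pct(s) for s in samples],
        under_target=[s.under_target for s in samples],
    )
    return df
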