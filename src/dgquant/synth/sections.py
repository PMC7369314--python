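"""Simulated systematic section series with a known true cell total.

Cells are placed by a uniform 3-D Poisson process through the *full* section
stack (every section, not just the sampled ones): the number of cells is
Poisson with mean density x total stack volume, and each cell falls into a
section with probability proportional to that section's slab volume.  The
returned series keeps only every ``interval``-th section (systematic sampling
with a seeded random start), so ``interval=1`` returns counts that sum to the
true total exactly — conservation holds by construction, not in expectation.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from dgquant.stereology import SectionRecord, SectionSeries, um_to_mm

__all__ = ["generate_section_series"]


def generate_section_series(
    true_density: float,
    area_profile: Sequence[float],
    thickness_um: float = 30.0,
    interval: int = 10,
    seed: int = 0,
    start_bregma_mm: float = -1.80,
) -> tuple[SectionSeries, int]:
    """Simulate one region's section series at a known density.

    Parameters
    ----------
    true_density : float
        Cells per mm^3, uniform through the stack.
    area_profile : sequence of float
        Traced area (mm^2) of every section in the full stack.
    thickness_um : float
        Section thickness in um.
    interval : int
        Keep every ``interval``-th section (random start within the first
        period, drawn from ``seed``).
    start_bregma_mm : float
        Bregma coordinate of the rostral face of the first section; sections
        advance caudally by one thickness each.

    Returns
    -------
    (series, true_total)
        The sampled :class:`SectionSeries` and the true number of cells placed
        in the whole stack.
    """
    areas = np.asarray(area_profile, dtype=float)
    if areas.size == 0:
        raise ValueError("area_profile must contain at least one section")
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    if thickness_um <= 0:
        raise ValueError("thickness_um must be positive")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if true_density < 0:
        raise ValueError("true_density must be non-negative")

    rng = np.random.default_rng(seed)
    slab_volumes = areas * um_to_mm(thickness_um)  # mm^3 per section
    total_volume = slab_volumes.sum()

    true_total = int(rng.poisson(true_density * total_volume)) if total_volume > 0 else 0
    if true_total > 0 and total_volume > 0:
        probs = slab_volumes / total_volume
        counts = rng.multinomial(true_total, probs)
    else:
        counts = np.zeros(areas.size, dtype=int)

    start = int(rng.integers(0, interval))
    idx = np.arange(start, areas.size, interval)
    if idx.size == 0:  # fewer sections than one sampling period
        idx = np.array([0])

    thickness_mm = um_to_mm(thickness_um)
    records = [
        SectionRecord(
            bregma_mm=start_bregma_mm - (i + 0.5) * thickness_mm,
            area_mm2=float(areas[i]),
            count=int(counts[i]),
        )
        for i in idx
    ]
    series = SectionSeries(
        records, sampling_interval=interval, section_thickness_um=thickness_um
    )
    return series, true_total
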