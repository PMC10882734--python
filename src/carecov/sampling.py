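"""Sample-size calculation and household selection in the sampling areas.

The sample size for estimating a proportion p with absolute precision d at
confidence 1−α is Cochran's n = z²_{1−α/2} p(1−p) / d², rounded up.
Households are drawn by seeded simple random sampling without replacement
from the points inside the dissolved sampling-area polygon; a household
that cannot be reached in the field is replaced by the nearest eligible
unselected household.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.stats import norm

from carecov.accessibility import SamplingAreaSet
from carecov.geojson import Feature


def cochran_sample_size(p: float, alpha: float = 0.05, d: float = 0.05) -> int:
    """Cochran sample size n = ⌈z²_{1−α/2} · p(1−p) / d²⌉.

    ``p`` the anticipated proportion, ``d`` the absolute margin of error,
    ``alpha`` the significance level (0.05 → z ≈ 1.959964).
    """
    if not 0 < p < 1:
        raise ValueError("p must be strictly between 0 and 1 (degenerate proportion)")
    if d <= 0:
        raise ValueError("margin d must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = norm.ppf(1 - alpha / 2)
    return math.ceil(z * z * p * (1 - p) / (d * d))


@dataclass
class SampleFrame:
    """Eligible households, the seeded selection, and any replacements."""

    households: list[Feature]
    selected: list[str] = field(default_factory=list)
    replacements: dict[str, str] = field(default_factory=dict)

    def _by_id(self) -> dict[str, Feature]:
        return {str(f.properties["household_id"]): f for f in self.households}

    def selected_features(self) -> list[Feature]:
        idx = self._by_id()
        return [idx[i] for i in self.selected]


def _inside(features: list[Feature], areas: SamplingAreaSet) -> list[Feature]:
    if areas.polygon.is_empty:
        return []
    shapely.prepare(areas.polygon)
    return [f for f in features if shapely.covers(areas.polygon, f.geometry)]


def draw_households(
    households: list[Feature],
    areas: SamplingAreaSet,
    n: int,
    seed: int = 0,
) -> SampleFrame:
    """Simple random sample of ``n`` distinct households inside the
    sampling areas (uniform, without replacement, reproducible by seed)."""
    eligible = _inside(households, areas)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(eligible):
        raise ValueError(f"requested {n} households but only {len(eligible)} are eligible")
    eligible = sorted(eligible, key=lambda f: str(f.properties["household_id"]))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False) if n else np.array([], dtype=int)
    selected = [str(eligible[i].properties["household_id"]) for i in idx]
    return SampleFrame(households=eligible, selected=selected)


def replace_unreachable(
    frame: SampleFrame,
    unreachable_id: str,
    candidates: list[Feature] | None = None,
) -> SampleFrame:
    """Swap an unreachable selected household for the nearest (Euclidean)
    unselected candidate; ties broken by household id order."""
    if unreachable_id not in frame.selected:
        raise ValueError(f"{unreachable_id!r} is not in the selection")
    if candidates is None:
        candidates = frame.households
    taken = set(frame.selected)
    pool = [f for f in candidates if str(f.properties["household_id"]) not in taken]
    if not pool:
        raise ValueError("no replacement candidate available")
    origin = frame._by_id()[unreachable_id].geometry
    best = min(
        pool,
        key=lambda f: (origin.distance(f.geometry), str(f.properties["household_id"])),
    )
    best_id = str(best.properties["household_id"])
    selected = [best_id if s == unreachable_id else s for s in frame.selected]
    repl = dict(frame.replacements)
    repl[unreachable_id] = best_id
    hh = frame.households
    if best not in hh:
        hh = hh + [best]
    return SampleFrame(households=hh, selected=selected, replacements=repl)
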