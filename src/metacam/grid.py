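"""Systematic CAM-group inclusion/exclusion experiments and the CRE summary.

To decide which component methods help a consensus ensemble, the methods
are partitioned into ``n`` groups by methodological family and every one
of the ``2^n`` inclusion/exclusion patterns is run as its own experiment:
a binary code whose leading bit is the first group (``100000`` = group A
only, ``111111`` = everything).  Each scorable experiment runs consensus
ensembling with an adaptive top-k search and records its best ROAD score.

The Cumulative Residual Effect (CRE) then attributes performance to
groups: each experiment's residual (its score minus the median score over
all scored experiments) is added to every group included in that
experiment.  A positive CRE means including the group tends to push
experiments above the median; a negative CRE means it drags them below.
Because CRE is built from residuals, reports from separate experiments
(different images / classes / models) aggregate by simple group-wise
summation.

With the default six groups each group appears in exactly 32 of the 64
codes.  The all-zero code (no methods at all) is enumerated for count
fidelity but is unscorable — an empty consensus is undefined — and is
excluded from the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cams import CAM_METHODS, CamResult, compute_cam
from .ensemble import DEFAULT_K_GRID, adaptive_threshold_search, drop_invalid
from .errors import ConfigurationError, InputError, ParameterError
from .models import ModelAdapter
from .road import RoadConfig

__all__ = [
    "CamGroup",
    "Experiment",
    "CREReport",
    "DEFAULT_GROUPS",
    "build_grid",
    "run_grid",
    "cre",
]


@dataclass(frozen=True)
class CamGroup:
    """A labelled, disjoint set of component CAM methods."""

    label: str
    members: tuple[str, ...]

    def __post_init__(self):
        for m in self.members:
            if m not in CAM_METHODS:
                raise ConfigurationError(f"group {self.label!r}: unknown method {m!r}")


#: Default grouping by methodological family.  The eigen methods are not in
#: the default grid (they are the most expensive per map and are better
#: studied by adding them explicitly); they remain addable via custom groups.
DEFAULT_GROUPS: tuple[CamGroup, ...] = (
    CamGroup("A", ("hirescam", "gradcam_elementwise")),
    CamGroup("B", ("gradcam", "gradcampp")),
    CamGroup("C", ("xgradcam",)),
    CamGroup("D", ("ablationcam", "scorecam")),
    CamGroup("E", ("layercam",)),
    CamGroup("F", ("fullgrad",)),
)


@dataclass(frozen=True)
class Experiment:
    """One inclusion/exclusion pattern, optionally scored.

    ``code``: binary string, leading bit = first group; ``1`` = included.
    ``scorable`` is False for the all-zero code and for runs whose every
    component map was invalid.  ``best_k`` / ``road`` are None until run.
    """

    code: str
    methods: tuple[str, ...]
    scorable: bool = True
    best_k: float | None = None
    road: float | None = None
    note: str | None = None


@dataclass(frozen=True)
class CREReport:
    """Group-wise cumulative residuals with the median they are taken against."""

    cre: dict[str, float] = field(default_factory=dict)
    median_score: float = 0.0
    n_scored: int = 0


def build_grid(groups: Sequence[CamGroup] = DEFAULT_GROUPS) -> list[Experiment]:
    """All ``2^n`` inclusion/exclusion experiments for ``n`` groups.

    Codes run from ``00...0`` to ``11...1`` in binary counting order; the
    all-zero code is flagged unscorable.  Groups must be pairwise disjoint.
    """
    n = len(groups)
    if not (1 <= n <= 16):
        raise ParameterError(f"need between 1 and 16 groups, got {n}")
    seen: set[str] = set()
    for g in groups:
        overlap = seen.intersection(g.members)
        if overlap:
            raise ConfigurationError(
                f"groups overlap on {sorted(overlap)} (group {g.label!r})"
            )
        seen.update(g.members)
    grid = []
    for i in range(2**n):
        code = format(i, f"0{n}b")
        methods = tuple(
            m for bit, g in zip(code, groups) if bit == "1" for m in g.members
        )
        grid.append(Experiment(code=code, methods=methods, scorable=bool(methods)))
    return grid


def run_grid(
    grid: Sequence[Experiment],
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    road_config: RoadConfig | None = None,
    seed: int = 0,
    progress: bool = False,
) -> list[Experiment]:
    """Score every scorable experiment in the grid.

    Component maps are computed once per unique method and shared across
    experiments.  Individual experiment failures (e.g. every included map
    invalid) are recorded as unscorable with a note; they never abort the
    grid.  Deterministic under fixed ``seed`` / ``road_config``.
    """
    road_config = road_config or RoadConfig()
    unique_methods = sorted({m for e in grid for m in e.methods})
    cam_cache: dict[str, CamResult] = {
        m: compute_cam(m, model, image, class_index=class_index, seed=seed)
        for m in unique_methods
    }
    out: list[Experiment] = []
    for e in grid:
        if not e.scorable:
            out.append(replace(e, note="empty method set"))
            continue
        try:
            survivors = drop_invalid([cam_cache[m] for m in e.methods])
            result = adaptive_threshold_search(
                [r.map for r in survivors],
                model,
                image,
                class_index,
                k_grid=k_grid,
                road_config=road_config,
            )
            scored = replace(
                e, best_k=result.best_k, road=result.scores_by_k[result.best_k]
            )
            out.append(scored)
        except Exception as exc:  # record, never abort the grid
            out.append(replace(e, scorable=False, note=str(exc)))
        if progress:
            print(f"[grid] {e.code}: {out[-1].road}", flush=True)
    return out


def cre(results: Sequence[Experiment], group_labels: Sequence[str] | None = None) -> CREReport:
    """Cumulative Residual Effect of each group over scored experiments.

    ``residual_i = road_i - median(road over scored experiments)``;
    ``CRE_g = sum of residual_i over experiments whose code includes g``.
    The median of an even count is the mean of the two middle values
    (numpy convention).  Reports from several grids aggregate by summing
    their per-group CRE values.
    """
    scored = [r for r in results if r.road is not None]
    if len(scored) < 2:
        raise InputError(f"need at least 2 scored experiments, got {len(scored)}")
    n_groups = len(scored[0].code)
    for r in scored:
        if len(r.code) != n_groups:
            raise InputError("inconsistent code lengths across experiments")
    if group_labels is None:
        group_labels = [chr(ord("A") + i) for i in range(n_groups)]
    elif len(group_labels) != n_groups:
        raise InputError("one label per code position required")
    scores = np.array([r.road for r in scored], dtype=np.float64)
    med = float(np.median(scores))
    totals = dict.fromkeys(group_labels, 0.0)
    for r, s in zip(scored, scores):
        resid = float(s) - med
        for bit, label in zip(r.code, group_labels):
            if bit == "1":
                totals[label] += resid
    return CREReport(cre=totals, median_score=med, n_scored=len(scored))
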