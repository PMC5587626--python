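"""Combined iterative registration-analysis + grouping loop.

Experimental peak lists mix populations with different positional
variances: a subset of peaks groups cleanly under tight tolerances while
another subset needs looser ones.  The combined algorithm treats the list
as a linear mixture of normal-like populations and peels them off tier by
tier: self-register the current peaks to estimate per-dimension stds,
group with those stds, remove the clustered peaks, and repeat on whatever
is left — each successive tier capturing a larger-variance population.

The loop stops when too few peaks remain to form a cluster, a tier forms
no new cluster, registration fails on the remainder, or a maximum number
of tiers is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grouping import GroupingConfig, GroupingResult, SpinSystemCluster, group
from .peaklist import DimensionStats, PeakList
from .registration import (
    InsufficientDataError,
    RegistrationConfig,
    RegistrationError,
    register,
)

__all__ = ["TierResult", "PipelineResult", "run_pipeline", "single_iteration_mode"]

#: Warm-start inflation: a later tier targets a larger-variance population,
#: so its registration starts from the previous tier's stds times this.
WARM_START_FACTOR = 3.0


@dataclass
class TierResult:
    tier: int
    stats: DimensionStats
    clusters: list[SpinSystemCluster]


@dataclass
class PipelineResult:
    tiers: list[TierResult]
    final_unclustered: frozenset[int]
    n_outer_iterations: int

    @property
    def clusters(self) -> list[SpinSystemCluster]:
        """All clusters across tiers (member indices refer to the original list)."""
        return [c for t in self.tiers for c in t.clusters]

    @property
    def unclustered(self) -> frozenset[int]:
        return self.final_unclustered

    def as_grouping_result(self) -> GroupingResult:
        return GroupingResult(clusters=self.clusters, unclustered=self.final_unclustered)


def _template(gcfg_template: GroupingConfig | None) -> tuple[float, int]:
    if gcfg_template is None:
        return 1e-4, 2
    return gcfg_template.p_value, gcfg_template.min_points


def run_pipeline(
    pl: PeakList,
    rcfg: RegistrationConfig | None = None,
    gcfg_template: GroupingConfig | None = None,
    max_outer: int = 5,
) -> PipelineResult:
    """Iterative self-registration + grouping over successive variance tiers.

    ``gcfg_template`` supplies the p-value and ``min_points`` (its stds are
    ignored: each tier's stds come from that tier's self-registration).
    Clusters returned carry the tier that produced them, and their member
    indices always refer to the original peak list.
    """
    rcfg = rcfg or RegistrationConfig()
    p_value, min_points = _template(gcfg_template)
    n = len(pl)
    if n < 2 * min_points:
        raise InsufficientDataError(
            f"pipeline needs at least {2 * min_points} peaks, got {n}"
        )

    tiers: list[TierResult] = []
    remaining = list(range(n))
    next_cluster_id = 0
    prev_stds: tuple[float, ...] | None = None
    outer = 0
    while outer < max_outer:
        if len(remaining) < 2 * min_points:
            break
        outer += 1
        sub = pl.subset(remaining)
        tier_cfg = rcfg
        if prev_stds is not None:
            tier_cfg = RegistrationConfig(
                tolerance_units=rcfg.tolerance_units,
                std_factor=rcfg.std_factor,
                initial_stds=tuple(s * WARM_START_FACTOR for s in prev_stds),
                convergence_tol=rcfg.convergence_tol,
                max_iterations=rcfg.max_iterations,
            )
        try:
            reg = register(sub, mode="self", cfg=tier_cfg)
        except RegistrationError:
            break
        gres = group(
            sub, GroupingConfig(stds=reg.stats.stds, p_value=p_value, min_points=min_points)
        )
        if not gres.clusters:
            break
        clusters = []
        for c in gres.clusters:
            clusters.append(
                SpinSystemCluster(
                    cluster_id=next_cluster_id,
                    member_indices=frozenset(remaining[i] for i in c.member_indices),
                    tier=outer,
                    stds_used=reg.stats.stds,
                )
            )
            next_cluster_id += 1
        tiers.append(TierResult(tier=outer, stats=reg.stats, clusters=clusters))
        remaining = sorted(
            remaining[i] for i in gres.unclustered
        )
        prev_stds = reg.stats.stds
        if not remaining:
            break
    return PipelineResult(
        tiers=tiers,
        final_unclustered=frozenset(remaining),
        n_outer_iterations=outer,
    )


def single_iteration_mode(
    pl: PeakList,
    rcfg: RegistrationConfig | None = None,
    gcfg_template: GroupingConfig | None = None,
) -> PipelineResult:
    """Exactly one self-registration + grouping pass (the uniform-tolerance
    baseline the iterative loop is compared against)."""
    if len(pl) == 0:
        raise InsufficientDataError("cannot run on an empty peak list")
    return run_pipeline(pl, rcfg=rcfg, gcfg_template=gcfg_template, max_outer=1)
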