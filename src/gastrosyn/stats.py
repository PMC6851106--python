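"""Statistical layer: Dm bootstrap, rank comparison, ANOVA + Dunnett.

The median dose of an in-vivo dose-response fit has no convenient
closed-form sampling distribution, so uncertainty is obtained by a
nonparametric bootstrap: animals are resampled with replacement within
each dose group (including the control), affected fractions recomputed
from resampled group means, and the median-effect line refitted.

Experimental vs theoretical Dm of a combination are compared with a
rank-based bootstrap test: the Mann-Whitney overlap statistic
P = Pr(Dm_exp,b > Dm_theo,b') over all replicate pairs, with the
two-sided bootstrap achieved-significance level p = 2*min(P, 1-P).
Unlike a literal two-sample rank test between replicate vectors, this
p-value does not sharpen as the (arbitrary) number of bootstrap
replicates grows; its power is set by the data, not by n_boot.

Damage areas across treatment groups are compared to the ulcerated
control with one-way ANOVA followed by Dunnett's many-to-one test
(simulation-based multivariate-t critical values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .median_effect import DEFAULT_CLAMP_EPS, fit_study
from .study import DoseResponseStudy

__all__ = [
    "BootstrapDm",
    "CompareDmResult",
    "bootstrap_dm",
    "additive_dm_bootstrap",
    "compare_dm",
    "damage_anova_dunnett",
]


@dataclass
class BootstrapDm:
    """Bootstrap distribution of a fitted median dose."""

    replicates: np.ndarray  # mg/kg, successful replicates only
    n_boot: int
    seed: int | None
    point_estimate: float
    ci95: tuple[float, float]
    n_failed: int = 0
    n_units: int = 6  # animals per group, used to calibrate comparisons

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if np.any(self.replicates <= 0):
            raise ValueError("bootstrap Dm replicates must be positive")


def _group_arrays(study: DoseResponseStudy) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    control = study.control_areas
    doses = study.dose_levels
    groups = [study.group_areas(d) for d in doses]
    return control, groups, doses


def bootstrap_dm(
    study: DoseResponseStudy,
    n_boot: int = 200,
    seed: int | None = 0,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
    variance_correction: bool = True,
) -> BootstrapDm:
    """Bootstrap the median dose by resampling animals within dose groups.

    Replicates whose refit is non-finite or has a non-positive slope are
    dropped and counted in ``n_failed``; more than 50% failures raises.

    ``variance_correction`` rescales log-replicates about their mean by
    sqrt(n/(n-1)) (n = smallest group size): the naive bootstrap of a
    group mean understates its variance by (n-1)/n, which matters at the
    n = 6 animals/group typical of these studies.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    control, groups, doses = _group_arrays(study)
    if control.size == 0:
        raise ValueError(f"missing control: study {study.treatment_id!r} has no dose-0 records")
    if len(doses) < 3:
        raise ValueError("need at least 3 dose levels to bootstrap a fit")

    nc = control.size
    ctrl_means = control[rng.integers(0, nc, size=(n_boot, nc))].mean(axis=1)
    group_means = np.empty((n_boot, len(groups)))
    for j, areas in enumerate(groups):
        n = areas.size
        group_means[:, j] = areas[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        fa = 1.0 - group_means / ctrl_means[:, None]
        fa = np.clip(fa, clamp_eps, 1.0 - clamp_eps)
        y = np.log10(fa / (1.0 - fa))
        x = np.log10(doses)
        xc = x - x.mean()
        slope = (y - y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
        intercept = y.mean(axis=1) - slope * x.mean()
        dm = 10.0 ** (-intercept / slope)

    ok = np.isfinite(dm) & (slope > 0) & (dm > 0)
    n_failed = int(n_boot - ok.sum())
    if n_failed > n_boot / 2:
        raise RuntimeError(
            f"unstable fit: {n_failed}/{n_boot} bootstrap replicates failed "
            f"for {study.treatment_id!r}"
        )
    replicates = dm[ok]

    n_units = int(min([nc] + [g.size for g in groups]))
    if variance_correction and n_units > 1 and replicates.size:
        log_rep = np.log(replicates)
        center = log_rep.mean()
        replicates = np.exp(center + np.sqrt(n_units / (n_units - 1)) * (log_rep - center))
        # exp() can under/overflow for extreme tail replicates; clip within
        # float range (rank-based comparisons only use the ordering)
        replicates = np.clip(replicates, 1e-300, 1e300)

    point = fit_study(study, clamp_eps=clamp_eps).dm_
    ci95 = tuple(np.percentile(replicates, [2.5, 97.5])) if replicates.size else (np.nan, np.nan)
    return BootstrapDm(
        replicates=replicates,
        n_boot=n_boot,
        seed=seed,
        point_estimate=float(point),
        ci95=(float(ci95[0]), float(ci95[1])),
        n_failed=n_failed,
        n_units=n_units,
    )


def additive_dm_bootstrap(boot1: BootstrapDm, boot2: BootstrapDm) -> BootstrapDm:
    """Bootstrap distribution of the additive expectation (Dm1 + Dm2)/2.

    Replicates are paired index-wise; the two bootstraps are independent,
    so the pairing is an arbitrary but valid coupling.
    """
    n = min(boot1.replicates.size, boot2.replicates.size)
    replicates = (boot1.replicates[:n] + boot2.replicates[:n]) / 2.0
    point = (boot1.point_estimate + boot2.point_estimate) / 2.0
    ci95 = tuple(np.percentile(replicates, [2.5, 97.5]))
    return BootstrapDm(
        replicates=replicates,
        n_boot=n,
        seed=None,
        point_estimate=float(point),
        ci95=(float(ci95[0]), float(ci95[1])),
        n_failed=boot1.n_failed + boot2.n_failed,
        n_units=min(boot1.n_units, boot2.n_units),
    )


@dataclass(frozen=True)
class CompareDmResult:
    statistic: float  # P(exp > theo), Mann-Whitney U / (n1*n2)
    p_value: float
    different: bool
    verdict: str  # "subadditive" | "synergistic" | "additive"


def compare_dm(exp: BootstrapDm, theo: BootstrapDm, alpha: float = 0.05) -> CompareDmResult:
    """Rank-based bootstrap comparison of experimental vs additive Dm.

    Verdict rule: the interaction is subadditive (antagonistic) if the
    experimental Dm is significantly above the additive expectation,
    synergistic if significantly below, additive otherwise.
    """
    x, y = exp.replicates, theo.replicates
    if x.size == 0 or y.size == 0:
        raise ValueError("both replicate sets must be non-empty")
    if x.std() == 0.0 and y.std() == 0.0:
        warnings.warn("zero-variance replicate sets; verdict from point comparison", stacklevel=2)
        if x[0] == y[0]:
            return CompareDmResult(0.5, 1.0, False, "additive")
        verdict = "subadditive" if x[0] > y[0] else "synergistic"
        return CompareDmResult(1.0 if x[0] > y[0] else 0.0, 0.0, True, verdict)
    u, _ = sps.mannwhitneyu(x, y, alternative="two-sided")
    p_gt = float(u) / (x.size * y.size)  # common-language overlap, ties half-counted
    p_value = min(1.0, 2.0 * min(p_gt, 1.0 - p_gt))
    different = p_value < alpha
    if not different:
        verdict = "additive"
    elif p_gt > 0.5:
        verdict = "subadditive"
    else:
        verdict = "synergistic"
    return CompareDmResult(statistic=p_gt, p_value=p_value, different=different, verdict=verdict)


def damage_anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
    seed: int | None = 0,
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett many-to-one comparison against control.

    Returns one row per treatment group with mean, SEM and the adjusted
    p-value of its comparison with the ulcerated control.  The omnibus
    ANOVA F and p are attached as frame attrs.
    """
    if len(groups) < 1:
        raise ValueError("need at least one treatment group")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    control = np.asarray(control, dtype=float)
    if control.size < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least 2 observations")
    f_stat, f_p = sps.f_oneway(control, *arrays.values())
    rng = np.random.default_rng(seed)
    res = sps.dunnett(*arrays.values(), control=control, random_state=rng)
    frame = pd.DataFrame(
        {
            "group": list(arrays),
            "mean_area_mm2": [a.mean() for a in arrays.values()],
            "sem_area_mm2": [a.std(ddof=1) / np.sqrt(a.size) for a in arrays.values()],
            "p_vs_control": np.asarray(res.pvalue, dtype=float),
        }
    )
    frame["significant"] = frame["p_vs_control"] < alpha
    frame.attrs["anova_F"] = float(f_stat)
    frame.attrs["anova_p"] = float(f_p)
    frame.attrs["alpha"] = alpha
    return frame
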