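"""Post-simulation metrics.

* **Knockout robustness** — how strongly the immune effector trajectory
  depends on any single signalling protein.  Each knockout removes one
  signalling protein with its edges; intact and knockout hosts live through
  the same life, infected at a fixed mid-window step by a non-disrupting
  parasite (replicates and is attacked, but has no target link), and the
  score is the mean absolute difference between the two effector
  trajectories.  Higher scores mean less robust networks.
* **Network features** — within-network connectivity (realized / possible
  legal ordered pairs), network size (independent hosts reported minus one to
  offset their extra starting protein), upstream pleiotropy (any evolved edge
  bridging the immune and developmental networks, shared effector excluded)
  and effector in-degree.
* **Quasi-binomial regression** — a logit-link binomial fit of the final
  shared-effector fraction on synchrony, resource condition and burn-in
  length, with standard errors inflated by the square root of the estimated
  dispersion (Pearson chi-square / residual df).
* **Geometric mean fitness** — ``exp(mean(log W))`` over a fitness series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import lifecycle, model_core as mc
from .config import ALTERNATING, PLENTIFUL, SCARCE, SYNCHRONOUS


# ---------------------------------------------------------------------------
# knockout robustness
# ---------------------------------------------------------------------------

@dataclass
class RobustnessResult:
    """Per-knockout effector divergences and their mean."""

    per_knockout: dict[int, float]
    summary: float


def knockout(host: mc.Host, protein_id: int) -> mc.Host:
    """Remove one protein and all its edges (an analytic probe, not evolution)."""
    victim = host.protein(protein_id)
    if victim.role != mc.SIGNAL:
        raise ValueError("only signalling proteins are knocked out")
    proteins = tuple(p for p in host.proteins if p.id != protein_id)
    edges = tuple(e for e in host.edges if protein_id not in (e.source, e.target))
    return dc_replace(host, proteins=proteins, edges=edges)


def knockout_robustness(
    host: mc.Host,
    schedule: lifecycle.SignallingSchedule,
    resource_limit: float,
    *,
    use_coef: float = mc.DEFAULT_USE_COEF,
    infection_step: int | None = None,
    equilibrium_steps: int = 5,
    inoculum: float = 0.5,
    signal_variant: str = "half-angle",
) -> RobustnessResult:
    """Mean |intact - knockout| immune effector divergence per knockout.

    Infection timing is fixed at the midpoint of the scenario's infection
    window so that intact/knockout differences reflect network structure, not
    timing noise.
    """
    signalling = [p for p in host.proteins if p.role == mc.SIGNAL]
    if not signalling:
        raise ValueError("host has no signalling protein to knock out")
    if infection_step is None:
        infection_step = schedule.midpoint_infection_step()

    def effector_life(target: mc.Host) -> np.ndarray:
        record = lifecycle.simulate_life(
            target,
            parasite_links=lifecycle.non_disrupting_links(target),
            schedule=schedule,
            resource_limit=resource_limit,
            infection_step=infection_step,
            use_coef=use_coef,
            equilibrium_steps=equilibrium_steps,
            inoculum=inoculum,
            signal_variant=signal_variant,
        )
        return record.life_series(target.immune_effector.id)

    intact = effector_life(host)
    scores = {}
    for protein in signalling:
        mutant = knockout(host, protein.id)
        scores[protein.id] = float(np.abs(intact - effector_life(mutant)).mean())
    return RobustnessResult(scores, float(np.mean(list(scores.values()))))


# ---------------------------------------------------------------------------
# network features
# ---------------------------------------------------------------------------

def most_common_genotype(population: list[mc.Host]) -> mc.Host:
    """Modal genotype under structural equality; ties go to first occurrence."""
    if not population:
        raise ValueError("empty population")
    counts: dict[mc.Host, int] = {}
    first: dict[mc.Host, int] = {}
    for i, host in enumerate(population):
        counts[host] = counts.get(host, 0) + 1
        first.setdefault(host, i)
    return max(counts, key=lambda h: (counts[h], -first[h]))


@dataclass
class NetworkFeatures:
    """Structural summary of one host genotype."""

    connectivity: float
    size: int
    upstream_pleiotropy: bool
    effector_in_degree: int


def network_features(host: mc.Host) -> NetworkFeatures:
    by_id = {p.id: p for p in host.proteins}
    within = [
        e
        for e in host.edges
        if mc.shares_network(by_id[e.source], by_id[e.target])
    ]
    possible = host.valid_pairs(cross_network=False)
    connectivity = len(within) / len(possible) if possible else 0.0

    size = len(host.proteins) - (1 if host.architecture == mc.INDEPENDENT else 0)

    upstream = False
    for e in host.edges:
        a, b = by_id[e.source], by_id[e.target]
        if mc.SHARED in (a.network, b.network):
            continue
        if a.network != b.network:
            upstream = True
            break

    effector = host.immune_effector.id
    in_degree = sum(1 for e in host.edges if e.target == effector)
    return NetworkFeatures(connectivity, size, upstream, in_degree)


# ---------------------------------------------------------------------------
# quasi-binomial regression
# ---------------------------------------------------------------------------

@dataclass
class QuasiBinomialResult:
    """Coefficients with dispersion-adjusted uncertainty."""

    params: pd.Series
    bse: pd.Series
    dispersion: float
    zvalues: pd.Series
    pvalues: pd.Series
    odds_ratios: pd.Series
    nobs: int
    dropped: tuple[str, ...]
    glm_result: object

    def summary(self) -> str:
        table = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.zvalues,
                "P>|z|": self.pvalues,
                "odds ratio": self.odds_ratios,
            }
        )
        lines = [
            "Quasi-binomial regression (logit link)",
            f"n = {self.nobs}, dispersion = {self.dispersion:.4f}",
            table.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.dropped:
            lines.append(f"dropped constant predictors: {', '.join(self.dropped)}")
        return "\n".join(lines)


def fit_quasibinomial(
    final_shared_fraction,
    synchrony,
    resources,
    burn_in,
) -> QuasiBinomialResult:
    """Fit ``shared fraction ~ synchrony + resources + burn-in``.

    Resources enter as two dummies against the scarce reference; burn-in is
    numeric in units of 250 generations.  The binomial GLM is fitted with a
    logit link, then standard errors are scaled by ``sqrt(dispersion)`` with
    dispersion estimated as Pearson chi-square over residual df.  Predictors
    with a single observed level are dropped (and reported); a rank-deficient
    design raises.
    """
    y = np.asarray(final_shared_fraction, dtype=float)
    if y.size == 0:
        raise ValueError("no observations")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    synchrony = np.asarray(synchrony)
    resources = np.asarray(resources)
    burn = np.asarray(burn_in, dtype=float)

    design = pd.DataFrame(
        {
            "intercept": np.ones_like(y),
            "synchronous": (synchrony == SYNCHRONOUS).astype(float),
            ALTERNATING: (resources == ALTERNATING).astype(float),
            PLENTIFUL: (resources == PLENTIFUL).astype(float),
            "burn_in_per_250": burn / 250.0,
        }
    )
    dropped = tuple(
        c for c in design.columns[1:] if design[c].nunique() == 1
    )
    design = design.drop(columns=list(dropped))
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError("design matrix is rank deficient (degenerate design)")

    glm = sm.GLM(y, design, family=sm.families.Binomial())
    fit = glm.fit()
    df_resid = fit.df_resid
    if df_resid <= 0:
        raise ValueError("not enough observations to estimate dispersion")
    pearson_chi2 = float(np.sum(fit.resid_pearson**2))
    dispersion = pearson_chi2 / df_resid
    bse = fit.bse * np.sqrt(dispersion)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.params / bse
    pvalues = pd.Series(
        2.0 * scipy.stats.norm.sf(np.abs(z)), index=fit.params.index
    )
    return QuasiBinomialResult(
        params=fit.params,
        bse=bse,
        dispersion=dispersion,
        zvalues=z,
        pvalues=pvalues,
        odds_ratios=np.exp(fit.params),
        nobs=int(y.size),
        dropped=dropped,
        glm_result=fit,
    )


def fit_quasibinomial_frame(table: pd.DataFrame) -> QuasiBinomialResult:
    """Convenience wrapper over a campaign results table."""
    return fit_quasibinomial(
        table["final_shared_fraction"],
        table["synchrony"],
        table["resources"],
        table["burn_in"],
    )


# ---------------------------------------------------------------------------
# geometric mean fitness
# ---------------------------------------------------------------------------

def geometric_mean_fitness(fitness_series) -> float:
    """``exp(mean(log W))``; requires strictly positive values."""
    values = np.asarray(fitness_series, dtype=float)
    if values.size == 0:
        raise ValueError("empty fitness series")
    if np.any(values <= 0):
        raise ValueError("geometric mean requires strictly positive fitness")
    return float(np.exp(np.mean(np.log(values))))
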