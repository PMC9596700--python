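"""Cohort experiment orchestration and generic statistics.

The central experiment: train a cohort of simulated individuals, and at
an early and a late checkpoint (i) cluster their gaze strategies into
two representative patterns, (ii) place each individual on the AB
pattern scale and measure its overall entropy (eye-movement
consistency), (iii) evaluate recognition accuracy, and (iv) relate
accuracy to pattern and to consistency.  Early in training consistency
(negative entropy-accuracy correlation) is the better predictor;
training then concentrates strategies, so entropy falls and its
variance shrinks by the late checkpoint.

The generic statistics (Pearson/partial correlation, pooled two-sample
t with Cohen's d, power-based minimum sample sizes for a regression
F-test and a one-tailed two-sample t-test) are thin layers over scipy;
the power calculators scan the sample size against the non-central F/t
distributions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .emhmm import overall_entropy, vhem_cluster
from .training import (
    Cohort,
    TrainConfig,
    evaluate_accuracy,
    run_cohort,
    simulate_individual_fixations,
)

__all__ = [
    "ExperimentReport",
    "run_experiment",
    "run_replicated_experiments",
    "correlation_and_regression",
    "two_sample_t",
    "required_n_regression",
    "required_n_ttest",
    "scaled_reference_config",
    "fast_experiment_config",
]


# ---------------------------------------------------------------------------
# generic statistics
# ---------------------------------------------------------------------------

def correlation_and_regression(x, y, covariate=None) -> dict:
    """Pearson (or partial) correlation and simple-regression R^2.

    With a covariate, the partial correlation of x and y controlling
    for it is computed from the residuals of the two simple
    regressions on the covariate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if covariate is not None:
        z = np.asarray(covariate, dtype=float)
        Z = np.column_stack([np.ones_like(z), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        if np.std(rx) < 1e-12 or np.std(ry) < 1e-12:
            raise ValueError("zero residual variance: partial correlation undefined")
        r = float(np.corrcoef(rx, ry)[0, 1])
        df = x.size - 3  # one covariate partialled out
        t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            raise ValueError("zero variance: correlation undefined")
        r, p = sps.pearsonr(x, y)
    return dict(r=float(r), r2=float(r**2), p=float(p))


def two_sample_t(a, b, one_tailed: bool = False) -> dict:
    """Pooled-variance independent two-sample t-test with Cohen's d.

    ``d`` uses the pooled SD; df = n_a + n_b - 2.  One-tailed tests the
    alternative mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 < 1e-300:
        if np.isclose(a.mean(), b.mean()):
            return dict(t=0.0, df=df, p=1.0, cohens_d=0.0)
        raise ValueError("zero pooled variance with unequal means")
    d = float((a.mean() - b.mean()) / np.sqrt(sp2))
    t = d * np.sqrt(na * nb / (na + nb))
    p = float(sps.t.sf(t, df)) if one_tailed else float(2 * sps.t.sf(abs(t), df))
    return dict(t=float(t), df=int(df), p=p, cohens_d=d)


def required_n_regression(n_predictors: int, f2: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Minimum total N for the overall F-test of a multiple regression.

    Scans N upward; at each N the test has df1 = n_predictors,
    df2 = N - n_predictors - 1 and non-centrality f2 * N.
    """
    if f2 <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("invalid effect size, alpha, or power")
    N = n_predictors + 2
    while True:
        df2 = N - n_predictors - 1
        crit = sps.f.isf(alpha, n_predictors, df2)
        achieved = sps.ncf.sf(crit, n_predictors, df2, f2 * N)
        if achieved >= power:
            return N
        N += 1
        if N > 1_000_000:
            raise RuntimeError("no attainable sample size found")


def required_n_ttest(d: float, alpha: float = 0.05, power: float = 0.8, one_tailed: bool = False) -> int:
    """Minimum total N (two equal groups) for an independent t-test.

    Scans per-group n; at each n the test has df = 2n - 2 and
    non-centrality d * sqrt(n / 2).  Returns 2n.
    """
    if d <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("invalid effect size, alpha, or power")
    n = 2
    while True:
        df = 2 * n - 2
        crit = sps.t.isf(alpha if one_tailed else alpha / 2, df)
        achieved = sps.nct.sf(crit, df, d * np.sqrt(n / 2.0))
        if achieved >= power:
            return 2 * n
        n += 1
        if n > 1_000_000:
            raise RuntimeError("no attainable sample size found")


# ---------------------------------------------------------------------------
# the cohort experiment
# ---------------------------------------------------------------------------

def scaled_reference_config(seed: int = 0) -> dict:
    """The shipped scaled-down counterpart of the full experiment.

    10 identities x 20 exemplars at 32x32 px, 16 individuals, 150
    epochs with checkpoints at 30 (partially trained) and 150
    (well trained), 10 replicate experiment seeds.
    """
    return dict(
        train=TrainConfig(
            n_identities=10,
            image_size=32,
            epochs=150,
            checkpoint_epochs=(30, 150),
            seed=seed,
        ),
        exemplars_per_identity=20,
        n_individuals=16,
        n_replicates=10,
        n_trials=50,
        cluster_restarts=10,
        n_virtual_samples=50,
    )


def fast_experiment_config(seed: int = 0) -> dict:
    """A smaller profile for quick, repeated experiment runs.

    8 identities x 12 exemplars at 32x32 px, 12 individuals, 40 epochs
    with checkpoints at 8 and 40, 5 replicates.  Chosen so a replicated
    experiment completes in minutes while preserving the early/late
    contrast the full design probes.
    """
    return dict(
        train=TrainConfig(
            n_identities=8,
            image_size=32,
            epochs=40,
            checkpoint_epochs=(8, 40),
            seed=seed,
        ),
        exemplars_per_identity=12,
        n_individuals=12,
        n_replicates=5,
        n_trials=40,
        cluster_restarts=3,
        n_virtual_samples=30,
    )


@dataclasses.dataclass
class ExperimentReport:
    """Per-checkpoint tables and summary statistics of one cohort run."""

    tables: dict  # epoch -> DataFrame(individual, cluster, ab_scale, entropy, accuracy)
    summaries: dict  # epoch -> dict of summary statistics
    checkpoint_epochs: tuple


def _analyse_checkpoint(cohort: Cohort, epoch: int, n_trials: int, seed: int,
                        cluster_restarts: int, n_virtual_samples: int) -> tuple:
    inds = [i for i in cohort.individuals if i is not None]
    strategies = [ind.checkpoint_strategy(epoch) for ind in inds]
    hmms = [s.effective_hmm(include_scale=True) for s in strategies]
    data_seqs = [
        np.stack([q.as_array() for q in simulate_individual_fixations(s, n_trials, seed=seed + 17 * j)])
        for j, s in enumerate(strategies)
    ]
    clusters = vhem_cluster(
        hmms,
        n_clusters=2,
        restarts=cluster_restarts,
        n_virtual_samples=n_virtual_samples,
        rng_seed=seed,
        data_sequences=data_seqs,
    )
    # orient pattern A = the cluster whose representative looks higher on the
    # face (smaller mean y): the analogue of the eyes-focused pattern
    rep_y = [float(np.mean(np.asarray(rep["means"])[:, 1])) for rep in clusters.representatives]
    flip = rep_y[0] > rep_y[1]
    assignment = clusters.assignment.copy()
    logliks = clusters.logliks.copy()
    if flip:
        assignment = 1 - assignment
        logliks = logliks[:, ::-1]
    scale = (logliks[:, 0] - logliks[:, 1]) / (np.abs(logliks[:, 0]) + np.abs(logliks[:, 1]))
    entropy = [overall_entropy(h, T=3).total for h in hmms]
    accuracy = [
        evaluate_accuracy(
            (ind.checkpoint_net(epoch), strat), cohort.stimuli, seed=seed + 23 * j
        )
        for j, (ind, strat) in enumerate(zip(inds, strategies))
    ]
    table = pd.DataFrame(
        dict(
            individual=[ind.seed for ind in inds],
            cluster=np.where(assignment == 0, "A", "B"),
            ab_scale=scale,
            entropy=entropy,
            accuracy=accuracy,
        )
    )
    summary: dict = dict(
        accuracy_mean_A=float(table.loc[table.cluster == "A", "accuracy"].mean()),
        accuracy_mean_B=float(table.loc[table.cluster == "B", "accuracy"].mean()),
        entropy_mean=float(table.entropy.mean()),
        entropy_var=float(table.entropy.var(ddof=1)),
    )
    a = table.loc[table.cluster == "A", "accuracy"].to_numpy()
    b = table.loc[table.cluster == "B", "accuracy"].to_numpy()
    try:
        summary["pattern_test"] = two_sample_t(a, b)
    except ValueError as exc:
        summary["pattern_test"] = dict(error=str(exc))
    for name, xcol in (("ab_scale", "ab_scale"), ("entropy", "entropy")):
        try:
            summary[f"accuracy_vs_{name}"] = correlation_and_regression(
                table[xcol].to_numpy(), table.accuracy.to_numpy()
            )
        except ValueError as exc:
            summary[f"accuracy_vs_{name}"] = dict(error=str(exc))
    return table, summary


def run_experiment(
    cohort: Cohort,
    checkpoint_epochs=None,
    n_trials: int = 50,
    seed: int = 0,
    cluster_restarts: int = 10,
    n_virtual_samples: int = 50,
) -> ExperimentReport:
    """Cluster, scale, entropy and accuracy at each checkpoint of a cohort."""
    if checkpoint_epochs is None:
        checkpoint_epochs = cohort.config.checkpoint_epochs
    tables, summaries, done = {}, {}, []
    for epoch in checkpoint_epochs:
        missing = [
            i for i, ind in enumerate(cohort.individuals)
            if ind is not None and epoch not in ind.checkpoints
        ]
        if missing:
            summaries[epoch] = dict(error=f"checkpoint {epoch} missing for individuals {missing}")
            continue
        tables[epoch], summaries[epoch] = _analyse_checkpoint(
            cohort, epoch, n_trials, seed, cluster_restarts, n_virtual_samples
        )
        done.append(epoch)
    return ExperimentReport(tables=tables, summaries=summaries, checkpoint_epochs=tuple(done))


def run_replicated_experiments(profile: dict, base_seed: int = 0, progress: bool = False) -> dict:
    """Run the experiment for several replicate seeds and summarise.

    Returns the per-replicate reports plus the two headline stochastic
    properties: how often the early-checkpoint entropy-accuracy
    correlation is negative, and how often mean entropy decreases from
    the early to the late checkpoint.
    """
    reports = []
    cfg: TrainConfig = profile["train"]
    early, late = min(cfg.checkpoint_epochs), max(cfg.checkpoint_epochs)
    neg_corr, entropy_drop = [], []
    for rep in range(profile["n_replicates"]):
        seed = base_seed + 1000 * rep
        train_cfg = dataclasses.replace(cfg, seed=seed)
        from .faces import generate_identity_prototypes, render_stimulus_set

        protos = generate_identity_prototypes(train_cfg.n_identities, seed, train_cfg.image_size)
        stimuli = render_stimulus_set(
            protos, exemplars_per_identity=profile["exemplars_per_identity"], rng_seed=seed + 1
        )
        cohort = run_cohort(
            train_cfg, n_individuals=profile["n_individuals"], stimuli=stimuli, seed0=seed + 100
        )
        report = run_experiment(
            cohort,
            n_trials=profile["n_trials"],
            seed=seed,
            cluster_restarts=profile["cluster_restarts"],
            n_virtual_samples=profile["n_virtual_samples"],
        )
        reports.append(report)
        r_early = report.summaries[early].get("accuracy_vs_entropy", {}).get("r")
        neg_corr.append(r_early is not None and r_early < 0)
        entropy_drop.append(
            report.summaries[late]["entropy_mean"] < report.summaries[early]["entropy_mean"]
        )
        if progress:
            print(f"replicate {rep + 1}/{profile['n_replicates']} done", flush=True)
    return dict(
        reports=reports,
        frac_negative_entropy_accuracy_corr_early=float(np.mean(neg_corr)),
        frac_entropy_decreases=float(np.mean(entropy_drop)),
        early_epoch=early,
        late_epoch=late,
    )
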