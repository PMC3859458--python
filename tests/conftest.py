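"""Shared fixtures and independent oracles.

The oracles here re-derive quantities by direct enumeration — explicit
risk sets for the partial likelihood, exhaustive tables for Fisher,
exhaustive rank assignments for the rank-sum test — and stay independent
of the package's vectorized implementations they are used to check.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from cutpointsurv import SimulationConfig, generate_trial
from cutpointsurv.pipeline import _standardize_cohort


# ---------------------------------------------------------------------------
# Enumeration oracle: Efron partial log-likelihood
# ---------------------------------------------------------------------------

def naive_efron_loglik(beta, X, time, event):
    """Direct risk-set enumeration of the Efron-ties partial log-likelihood."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    eta = X @ beta
    ll = 0.0
    for tj in sorted(set(time[event == 1])):
        D = np.flatnonzero((time == tj) & (event == 1))
        R = np.flatnonzero(time >= tj)
        d = len(D)
        sR = np.exp(eta[R]).sum()
        sD = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD)
    return ll


def _batch_efron_loglik(B, X, time, event):
    """naive_efron_loglik vectorized over a batch of coefficient vectors."""
    E = X @ B.T  # (n, m)
    W = np.exp(E - E.max(axis=0))
    logshift = E.max(axis=0)
    ll = np.zeros(B.shape[0])
    for tj in sorted(set(time[event == 1])):
        D = (time == tj) & (event == 1)
        R = time >= tj
        d = int(D.sum())
        sR = W[R].sum(axis=0)
        sD = W[D].sum(axis=0)
        ll += E[D].sum(axis=0)
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD) + logshift
    return ll


def grid_max_loglik(X, time, event, lo=-4.0, hi=4.0, steps=15, refinements=6):
    """Maximize the enumerated partial likelihood by dense grid search.

    Works for up to 3 coefficients; each refinement zooms the grid around
    the current argmax, driving the final step size below 1e-4.
    """
    X = np.atleast_2d(np.asarray(X, float))
    p = X.shape[1]
    centers = np.zeros(p)
    half = (hi - lo) / 2.0
    best_ll, best_beta = -np.inf, centers
    for _ in range(refinements):
        axes = [np.linspace(c - half, c + half, steps) for c in centers]
        B = np.array(list(itertools.product(*axes)))
        lls = _batch_efron_loglik(B, X, time, event)
        i = int(np.argmax(lls))
        best_ll, best_beta = float(lls[i]), B[i]
        centers = best_beta
        half = 2.0 * (2 * half / (steps - 1))  # keep a margin of two old steps
    return best_ll, best_beta


# ---------------------------------------------------------------------------
# Enumeration oracles: Fisher and rank-sum
# ---------------------------------------------------------------------------

def fisher_enum_p(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins whose probability <= the observed."""
    from math import comb

    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def ranksum_enum_p(x, y):
    """Exact two-sided rank-sum p by exhausting all label assignments."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def six_patient_fixture():
    """Tiny survival dataset with a tie and censoring, one binary covariate."""
    return {
        "time": np.array([2.0, 3.0, 3.0, 5.0, 7.0, 9.0]),
        "event": np.array([1, 1, 1, 0, 1, 1]),
        "x": np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0]),
    }


def null_config(seed, n=300):
    """Generator config with no treatment or covariate effects."""
    return SimulationConfig(
        n_patients=n,
        seed=seed,
        frac_stage_iiib=0.0,
        allocation_ratio=(1, 1),
        regimen_scheme="single-agent-control",
        log_hr_treatment_low=0.0,
        log_hr_treatment_high=0.0,
        log_hr_covariates={k: 0.0 for k in
                           ("age_years", "sex_female", "histology_squamous", "histology_other")},
    )


def recovery_config(seed, n=400, quantile=0.30):
    """Strong-interaction scenario: treatment HR 0.5 below c*, 1.5 above."""
    return SimulationConfig(
        n_patients=n,
        seed=seed,
        frac_stage_iiib=0.0,
        allocation_ratio=(1, 1),
        regimen_scheme="single-agent-control",
        true_cutpoint_quantile=quantile,
        log_hr_treatment_low=float(np.log(0.5)),
        log_hr_treatment_high=float(np.log(1.5)),
    )


def standardized_null_cohort(seed, n=300):
    df, _ = _standardize_cohort(generate_trial(null_config(seed, n)).records, 1.4826)
    return df


def true_cutoff_std(dataset, params):
    """Latent raw threshold mapped to the standardized log2 scale."""
    p = params["ercc1_std"]
    return (np.log2(dataset.provenance["true_cutpoint_raw"]) - p.center) / p.scale
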