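"""Model evaluation for the matched case-control design.

Cross-validation follows the case-control rank scheme of habitat/step
selection studies: strata are split into k folds; on each held-out
stratum the case's score rank among its own alternatives is recorded;
ranks are pooled into equal-width bins and the bin index is
Spearman-correlated with the observed case frequency per bin.  A
well-calibrated model concentrates cases in the top-rank bins, giving a
strongly decreasing frequency profile; the reported r is the negated
Spearman correlation so that good models score positive.  The chance
baseline repeats the tally with a uniformly drawn alternative standing
in for the case.

Variable importance uses a cheap randomization: each term's values are
permuted across all rows (product terms recomputed from permuted
factors) and the conditional log-likelihood is re-evaluated at the
*fitted* coefficients; the mean log-likelihood drop over permutations is
the raw importance.  Both raw and sum-normalized values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ssf_model import ClogitFit, _stratum_layout, build_design, clogit_loglik, fit_clogit


@dataclass
class CVResult:
    r_observed_mean: float
    r_observed_min: float
    r_observed_max: float
    r_chance_mean: float
    r_chance_min: float
    r_chance_max: float
    n_reps: int
    k: int
    n_bins: int
    n_failed: int = 0
    r_observed: np.ndarray | None = None
    r_chance: np.ndarray | None = None

    def to_dict(self) -> dict:
        return dict(
            r_observed_mean=self.r_observed_mean,
            r_observed_min=self.r_observed_min,
            r_observed_max=self.r_observed_max,
            r_chance_mean=self.r_chance_mean,
            r_chance_min=self.r_chance_min,
            r_chance_max=self.r_chance_max,
            n_reps=self.n_reps,
            k=self.k,
            n_bins=self.n_bins,
            n_failed=self.n_failed,
        )


@dataclass
class ImportanceResult:
    terms: list[str]
    raw: np.ndarray  # mean log-likelihood drop per term
    relative: np.ndarray  # raw / sum(raw), clipped at 0
    n_permutations: int

    def to_dict(self) -> dict:
        return dict(
            terms=list(self.terms),
            raw={t: float(v) for t, v in zip(self.terms, self.raw)},
            relative={t: float(v) for t, v in zip(self.terms, self.relative)},
            n_permutations=self.n_permutations,
        )


def _rank_to_bin(rank: float, size: int, n_bins: int) -> int:
    """Equal-width bin (1..n_bins) of a within-stratum rank (1 = best score).

    Ranks map through the centered quantile (rank - 0.5)/size, so when the
    stratum size is not a multiple of n_bins the surplus rank lands in a
    central bin rather than systematically in an extreme one (which would
    bias the rank-frequency correlation even for a null model).
    """
    b = int(np.ceil((rank - 0.5) / size * n_bins))
    return min(max(b, 1), n_bins)


def _spearman_adherence(bin_counts: np.ndarray) -> float:
    """Negated Spearman r of bin index vs case frequency (positive = good model).

    Degenerate rankings where every case lands in a single bin carry no
    rank-order information for Spearman (all other counts tie at zero);
    by convention they score +1 in the best bin and -1 in the worst.
    """
    n_bins = len(bin_counts)
    if np.all(bin_counts == bin_counts[0]):
        return 0.0
    nonzero = np.flatnonzero(bin_counts)
    if len(nonzero) == 1:
        if nonzero[0] == 0:
            return 1.0
        if nonzero[0] == n_bins - 1:
            return -1.0
    r, _ = stats.spearmanr(np.arange(1, n_bins + 1), bin_counts)
    return float(-r)


def kfold_case_control_cv(
    steps: pd.DataFrame,
    terms: list[str],
    k: int = 5,
    n_bins: int = 10,
    reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> CVResult:
    """Case-control k-fold cross-validation with a chance baseline.

    One adherence r per repetition, pooled over folds; repetitions whose
    fold fits fail are excluded and counted in ``n_failed``.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    stratum_ids = steps["stratum_id"].unique()
    if len(stratum_ids) < k * 2:
        raise ValueError(f"too few strata ({len(stratum_ids)}) for {k}-fold CV")
    r_obs, r_cha = [], []
    n_failed = 0
    for _rep in range(reps):
        perm = rng.permutation(stratum_ids)
        folds = np.array_split(perm, k)
        obs_counts = np.zeros(n_bins)
        cha_counts = np.zeros(n_bins)
        failed = False
        for fold in folds:
            in_fold = steps["stratum_id"].isin(fold)
            train = steps[~in_fold]
            test = steps[in_fold]
            try:
                fit = fit_clogit(train, terms)
                if not fit.converged:
                    raise RuntimeError("fold fit did not converge")
            except Exception:
                failed = True
                break
            scores = build_design(test, terms) @ fit.beta
            for _, grp_idx in test.groupby("stratum_id").indices.items():
                grp = test.iloc[grp_idx]
                s = scores[grp_idx]
                ranks = stats.rankdata(-s, method="average")
                size = len(grp)
                case_rank = float(ranks[grp["is_case"].to_numpy(bool)][0])
                obs_counts[_rank_to_bin(case_rank, size, n_bins) - 1] += 1
                alt_positions = np.flatnonzero(~grp["is_case"].to_numpy(bool))
                pick = alt_positions[rng.integers(len(alt_positions))]
                cha_counts[_rank_to_bin(float(ranks[pick]), size, n_bins) - 1] += 1
        if failed:
            n_failed += 1
            continue
        r_obs.append(_spearman_adherence(obs_counts))
        r_cha.append(_spearman_adherence(cha_counts))
    r_obs = np.array(r_obs)
    r_cha = np.array(r_cha)
    if len(r_obs) == 0:
        raise RuntimeError("all cross-validation repetitions failed")
    return CVResult(
        r_observed_mean=float(r_obs.mean()),
        r_observed_min=float(r_obs.min()),
        r_observed_max=float(r_obs.max()),
        r_chance_mean=float(r_cha.mean()),
        r_chance_min=float(r_cha.min()),
        r_chance_max=float(r_cha.max()),
        n_reps=len(r_obs),
        k=k,
        n_bins=n_bins,
        n_failed=n_failed,
        r_observed=r_obs,
        r_chance=r_cha,
    )


def permutation_importance(
    steps: pd.DataFrame,
    fit: ClogitFit,
    n_perm: int = 10,
    rng: np.random.Generator | int | None = None,
) -> ImportanceResult:
    """Permutation importance of each fitted term (no refitting).

    Main-effect columns are shuffled across all rows and any interaction
    involving them is recomputed from the shuffled factor; interaction
    terms themselves are shuffled as columns.  Importance is the mean
    drop in conditional log-likelihood at the fitted coefficients.
    """
    if not fit.converged:
        raise ValueError("permutation importance needs a converged fit")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    y = steps["is_case"].to_numpy(bool)
    groups = steps["stratum_id"].to_numpy()
    order, starts, counts, case_pos = _stratum_layout(groups, y)

    def ll_of(df: pd.DataFrame) -> float:
        X = build_design(df, fit.terms)[order]
        ll, _, _ = clogit_loglik(fit.beta, X, starts, counts, case_pos)
        return ll

    ll_base = ll_of(steps)
    raw = np.zeros(len(fit.terms))
    n = len(steps)
    for i, term in enumerate(fit.terms):
        drops = []
        for _ in range(n_perm):
            shuffled = steps.copy()
            perm = rng.permutation(n)
            if ":" in term:
                a, b = term.split(":", 1)
                prod = (steps[a].to_numpy(float) * steps[b].to_numpy(float))[perm]
                col = f"__perm_{a}_{b}"
                shuffled[col] = prod
                terms_mod = [col if t == term else t for t in fit.terms]
                X = build_design(shuffled, terms_mod)[order]
                ll, _, _ = clogit_loglik(fit.beta, X, starts, counts, case_pos)
            else:
                shuffled[term] = steps[term].to_numpy()[perm]
                ll = ll_of(shuffled)
            drops.append(ll_base - ll)
        raw[i] = float(np.mean(drops))
    total = raw.clip(min=0.0).sum()
    relative = raw.clip(min=0.0) / total if total > 0 else np.zeros_like(raw)
    return ImportanceResult(
        terms=list(fit.terms), raw=raw, relative=relative, n_permutations=n_perm
    )
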