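"""Posterior summarization: pruning empty components of the overfitted
mixture, relabeling draws across the label-switching symmetry, modal
consumption patterns, the global-allocation heatmap, and survey-weighted
descriptive statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataError
from .model import PosteriorSamples


class PruningError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Relabeling machinery
# ---------------------------------------------------------------------------

def _tv_cost(theta_a: np.ndarray, theta_b: np.ndarray) -> np.ndarray:
    """(Ka, Kb) mean total-variation distance between pattern rows."""
    # theta_*: (K, p, d); TV per item = 0.5 * L1 over levels, averaged over p
    diff = np.abs(theta_a[:, None] - theta_b[None, :])  # (Ka, Kb, p, d)
    return 0.5 * diff.sum(axis=-1).mean(axis=-1)


def _greedy_match(cost: np.ndarray) -> np.ndarray:
    """Greedy assignment: perm[b] = index in `a` matched to reference b."""
    K = cost.shape[0]
    cost = cost.copy()
    perm = np.empty(K, dtype=np.int64)
    for _ in range(K):
        a, b = np.unravel_index(np.argmin(cost), cost.shape)
        perm[b] = a
        cost[a, :] = np.inf
        cost[:, b] = np.inf
    return perm


def relabel_component_draws(theta: np.ndarray, occupancy: np.ndarray,
                            threshold: float = 0.05):
    """Prune and relabel the component draws of one mixture family.

    Parameters
    ----------
    theta : (T, K, p, d) pattern-row draws.
    occupancy : (T, K) per-draw occupancy fractions.
    threshold : components whose posterior-median occupancy falls below this
        are dropped ("empty" components of the overfitted mixture).

    Every draw is first aligned to the final draw by greedy total-variation
    matching of the pattern rows (so arbitrary per-draw label permutations
    are undone), occupancy is computed on the aligned draws, components are
    pruned at the threshold, and the survivors are ordered by descending
    mean occupancy.

    Returns
    -------
    kept : surviving component roles, expressed as labels of the final
        (reference) draw, in output order.
    perms : (T, K') per-draw map, column k holds the original label that
        plays role k in draw t after matching.
    theta_rel, occ_rel : relabeled draw arrays, components ordered by
        descending mean occupancy.
    """
    T, K = occupancy.shape
    ref = theta[-1]  # last draw as matching reference
    perms = np.empty((T, K), dtype=np.int64)
    theta_rel = np.empty_like(theta)
    occ_rel = np.empty_like(occupancy)
    for t in range(T):
        m = _greedy_match(_tv_cost(theta[t], ref))  # m[role] = label in t
        perms[t] = m
        theta_rel[t] = theta[t, m]
        occ_rel[t] = occupancy[t, m]
    med_occ = np.median(occ_rel, axis=0)
    kept = np.flatnonzero(med_occ >= threshold)
    if kept.size == 0:
        raise PruningError(
            f"all {K} components fall below occupancy threshold "
            f"{threshold}; reduce the threshold")
    order = kept[np.argsort(-occ_rel[:, kept].mean(axis=0), kind="stable")]
    return order, perms[:, order], theta_rel[:, order], occ_rel[:, order]


def occupancy_draws(labels: np.ndarray, K: int,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """(T, K) fraction of (optionally masked) persons in each component."""
    T = labels.shape[0]
    sub = labels if mask is None else labels[:, mask]
    denom = sub.shape[1]
    out = np.empty((T, K))
    for t in range(T):
        out[t] = np.bincount(sub[t], minlength=K) / denom
    return out


# ---------------------------------------------------------------------------
# Pattern summaries
# ---------------------------------------------------------------------------

def modal_patterns(theta_mean: np.ndarray):
    """Modal consumption level per (pattern, item) with its probability.

    Ties are broken toward the lower level and flagged.  Returns
    ``(modal_levels, modal_probs, tie_flags)`` with levels 1-based.
    """
    modal0 = np.argmax(theta_mean, axis=-1)
    modal_probs = np.take_along_axis(theta_mean, modal0[..., None],
                                     axis=-1)[..., 0]
    ties = (np.isclose(theta_mean, modal_probs[..., None])).sum(axis=-1) > 1
    return modal0 + 1, modal_probs, ties


def allocation_heatmap(samples: PosteriorSamples) -> dict:
    """Posterior probability that each item follows the global process,
    by subgroup: a (p, S) matrix.

    Two estimates are returned: ``"G"`` averages the per-draw fraction of
    persons in the subgroup whose item indicator was global, and ``"nu"``
    averages the sampled allocation probabilities.  They agree up to
    Monte-Carlo error.
    """
    T, n, p = samples.G.shape
    S = len(samples.subgroup_names)
    g_est = np.empty((p, S))
    for s in range(S):
        mask = samples.subgroup == s + 1
        g_est[:, s] = samples.G[:, mask, :].mean(axis=(0, 1))
    nu_est = samples.nu.mean(axis=0).T  # (p, S)
    return {"G": g_est, "nu": nu_est}


@dataclass
class PatternSummary:
    """Pruned, relabeled posterior summary of the fitted model."""

    n_global_nonempty: int
    n_local_nonempty: list
    pi_mean: np.ndarray                # (K0',)
    lam_mean: list                     # per subgroup (Ks'_s,)
    theta0_mean: np.ndarray            # (K0', p, d)
    theta1_mean: list                  # per subgroup (Ks'_s, p, d)
    modal_global: np.ndarray           # (K0', p) levels
    modal_global_prob: np.ndarray
    modal_global_ties: np.ndarray
    modal_local: list                  # per subgroup (Ks'_s, p)
    modal_local_prob: list
    modal_local_ties: list
    membership_global: np.ndarray      # (n, K0') posterior membership
    membership_local: list             # per subgroup (n_s, Ks'_s)
    heatmap_G: np.ndarray              # (p, S)
    heatmap_nu: np.ndarray             # (p, S)
    occupancy_threshold: float
    item_names: list = field(default_factory=list)
    subgroup_names: list = field(default_factory=list)

    def modal_global_frame(self) -> pd.DataFrame:
        rows = []
        K, p = self.modal_global.shape
        for k in range(K):
            for j in range(p):
                rows.append({
                    "pattern": f"global_{k + 1}",
                    "item": self.item_names[j],
                    "modal_level": int(self.modal_global[k, j]),
                    "modal_probability": float(self.modal_global_prob[k, j]),
                    "tie": bool(self.modal_global_ties[k, j]),
                })
        return pd.DataFrame(rows)

    def modal_local_frame(self) -> pd.DataFrame:
        rows = []
        for s, name in enumerate(self.subgroup_names):
            Ks, p = self.modal_local[s].shape
            for k in range(Ks):
                for j in range(p):
                    rows.append({
                        "pattern": f"{name}_local_{k + 1}",
                        "subgroup": name,
                        "item": self.item_names[j],
                        "modal_level": int(self.modal_local[s][k, j]),
                        "modal_probability":
                            float(self.modal_local_prob[s][k, j]),
                        "tie": bool(self.modal_local_ties[s][k, j]),
                    })
        return pd.DataFrame(rows)

    def heatmap_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heatmap_G, columns=self.subgroup_names)
        df.insert(0, "item", self.item_names)
        return df


def _membership(labels_rel_counts: np.ndarray) -> np.ndarray:
    rows = labels_rel_counts.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return labels_rel_counts / rows


def prune_and_relabel(samples: PosteriorSamples,
                      occupancy_threshold: float = 0.05) -> PatternSummary:
    """Turn raw draws into the reported pattern summary.

    Global and per-subgroup local mixtures are pruned at the occupancy
    threshold (posterior-median fraction of the relevant population),
    relabeled per draw by greedy total-variation matching of the pattern
    rows against the final draw, ordered by descending mean occupancy, and
    averaged.  Membership probabilities are computed from the relabeled
    class-label draws; pruned-component draws are dropped and rows
    renormalized.
    """
    T = samples.n_draws
    K0 = samples.pi.shape[1]
    S, Ks = samples.lam.shape[1:]
    n = samples.z.shape[1]
    p = samples.theta0.shape[2]
    d = samples.theta0.shape[3]

    # ---- global family.  When (nearly) every item localizes, the global
    # classes see almost no data: their labels churn and no component
    # clears the occupancy threshold.  That is a legitimate finding ("no
    # nonempty global pattern"), not an error, so the global summary
    # degrades to zero patterns; an error is raised only if the local
    # families are empty as well.
    occ0 = occupancy_draws(samples.z, K0)
    try:
        kept0, perms0, theta0_rel, occ0_rel = relabel_component_draws(
            samples.theta0, occ0, occupancy_threshold)
        K0k = perms0.shape[1]
        theta0_mean = theta0_rel.mean(axis=0)
        pi_mean = np.array(
            [samples.pi[t, perms0[t]] for t in range(T)]).mean(0)
        member0 = np.zeros((n, K0k))
        for t in range(T):
            inv = {orig: k for k, orig in enumerate(perms0[t])}
            mapped = np.array([inv.get(int(h), -1) for h in samples.z[t]])
            for k in range(K0k):
                member0[:, k] += mapped == k
        member0 = _membership(member0)
        global_empty = False
    except PruningError:
        K0k = 0
        theta0_mean = np.empty((0, p, d))
        pi_mean = np.empty(0)
        member0 = np.empty((n, 0))
        global_empty = True

    # ---- local families
    lam_mean, theta1_mean = [], []
    modal_loc, modal_loc_p, modal_loc_t = [], [], []
    member_loc, n_local = [], []
    for s in range(S):
        mask = samples.subgroup == s + 1
        occ1 = occupancy_draws(samples.c, Ks, mask=mask)
        try:
            kept1, perms1, theta1_rel, occ1_rel = relabel_component_draws(
                samples.theta1[:, s], occ1, occupancy_threshold)
        except PruningError:
            n_local.append(0)
            theta1_mean.append(np.empty((0, p, d)))
            lam_mean.append(np.empty(0))
            modal_loc.append(np.empty((0, p), dtype=int))
            modal_loc_p.append(np.empty((0, p)))
            modal_loc_t.append(np.empty((0, p), dtype=bool))
            member_loc.append(np.empty((int(mask.sum()), 0)))
            continue
        Ksk = perms1.shape[1]
        n_local.append(Ksk)
        th_mean = theta1_rel.mean(axis=0)
        theta1_mean.append(th_mean)
        lam_mean.append(np.array(
            [samples.lam[t, s, perms1[t]] for t in range(T)]).mean(0))
        ml, mp, mt = modal_patterns(th_mean)
        modal_loc.append(ml)
        modal_loc_p.append(mp)
        modal_loc_t.append(mt)
        c_sub = samples.c[:, mask]
        mem = np.zeros((mask.sum(), Ksk))
        for t in range(T):
            inv = {orig: k for k, orig in enumerate(perms1[t])}
            mapped = np.array([inv.get(int(l), -1) for l in c_sub[t]])
            for k in range(Ksk):
                mem[:, k] += mapped == k
        member_loc.append(_membership(mem))

    if global_empty and all(k == 0 for k in n_local):
        raise PruningError(
            "no global or local component clears occupancy threshold "
            f"{occupancy_threshold}; reduce the threshold")
    mg, mgp, mgt = modal_patterns(theta0_mean) if K0k else (
        np.empty((0, p), dtype=int), np.empty((0, p)),
        np.empty((0, p), dtype=bool))
    heat = allocation_heatmap(samples)
    return PatternSummary(
        n_global_nonempty=K0k,
        n_local_nonempty=n_local,
        pi_mean=pi_mean,
        lam_mean=lam_mean,
        theta0_mean=theta0_mean,
        theta1_mean=theta1_mean,
        modal_global=mg, modal_global_prob=mgp, modal_global_ties=mgt,
        modal_local=modal_loc, modal_local_prob=modal_loc_p,
        modal_local_ties=modal_loc_t,
        membership_global=member0,
        membership_local=member_loc,
        heatmap_G=heat["G"], heatmap_nu=heat["nu"],
        occupancy_threshold=occupancy_threshold,
        item_names=list(samples.item_names),
        subgroup_names=list(samples.subgroup_names),
    )


# ---------------------------------------------------------------------------
# Survey-weighted descriptives
# ---------------------------------------------------------------------------

@dataclass
class WeightedSummary:
    """Horvitz-Thompson weighted estimates per stratum with bootstrap SEs.

    ``table`` has one row per (stratum, variable) plus an overall row set;
    the variability method is a person-level bootstrap (design-based
    strata/PSU variance estimation is intentionally not implemented and the
    metadata says so).
    """

    table: pd.DataFrame
    method: str = "horvitz-thompson point estimates; person-level bootstrap SE"


def weighted_descriptives(table: pd.DataFrame, weights, strata=None,
                          n_boot: int = 200, seed: int = 0) -> WeightedSummary:
    """Weighted means/proportions of each numeric column, by stratum.

    Missing values are dropped per variable (the person stays in the other
    variables' summaries).  Equal weights reduce exactly to unweighted
    means; rescaling all weights by a constant changes nothing.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise DataError("negative survey weights")
    if len(w) != len(table):
        raise DataError("weights length does not match table")
    strata = (np.asarray(strata) if strata is not None
              else np.array(["overall"] * len(table)))
    rng = np.random.default_rng(seed)
    rows = []
    levels = ["overall"] + [s for s in pd.unique(strata) if s != "overall"]
    for level in levels:
        mask = np.ones(len(table), bool) if level == "overall" \
            else strata == level
        for colname in table.columns:
            x = pd.to_numeric(table[colname], errors="coerce").to_numpy(
                dtype=float)
            ok = mask & ~np.isnan(x) & (w > 0)
            if ok.sum() == 0:
                rows.append({"stratum": level, "variable": colname,
                             "estimate": np.nan, "se": np.nan,
                             "n": 0})
                continue
            xi, wi = x[ok], w[ok]
            est = float(np.sum(wi * xi) / np.sum(wi))
            idx = np.arange(ok.sum())
            boots = np.empty(n_boot)
            for b in range(n_boot):
                bi = rng.integers(0, len(idx), len(idx))
                boots[b] = np.sum(wi[bi] * xi[bi]) / np.sum(wi[bi])
            rows.append({"stratum": level, "variable": colname,
                         "estimate": est, "se": float(boots.std(ddof=1)),
                         "n": int(ok.sum())})
    return WeightedSummary(table=pd.DataFrame(rows))
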