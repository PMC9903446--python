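"""Hierarchical analysis of molecular variance (AMOVA) with permutation tests.

Two-level Excoffier-style AMOVA for haploid data: squared pairwise
distances are partitioned into variance components Va (among groups), Vb
(among populations within groups) and Vc (within populations), from which
the fixation indices follow:

    Phi_CT = Va / (Va + Vb + Vc)
    Phi_SC = Vb / (Vb + Vc)
    Phi_ST = (Va + Vb) / (Va + Vb + Vc)

Sums of squares come from pair sums: for any set S of individuals,
SS(S) = (1/|S|) * sum_{i<j in S} d2_ij. Significance uses three
non-parametric permutation schemes: individuals among populations within
groups (Phi_SC), whole populations among groups (Phi_CT), and individuals
among populations ignoring groups (Phi_ST). Permutation p-values are
(k + 1)/(n_perm + 1), counting permuted statistics >= the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import MISSING


@dataclass
class DistanceMatrix:
    """Symmetric matrix of (squared) pairwise distances with row labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)


def _pairwise_differences(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(
            "nt_differences mode needs equal-length (aligned) sequences"
        )
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x not in MISSING and y not in MISSING
    )


def distance_matrix(
    records,
    mode: str = "haplotype_binary",
    assignments: dict[str, str] | None = None,
) -> DistanceMatrix:
    """Squared pairwise distances between records.

    ``haplotype_binary``: d2 = 0 between members of the same haplotype
    (identical sequences, or identical ``assignments`` labels when given),
    1 otherwise. ``nt_differences``: d2 = (number of differing aligned
    positions)^2, missing states ignored.
    """
    labels = [r.id for r in records]
    n = len(labels)
    d2 = np.zeros((n, n))
    if mode == "haplotype_binary":
        if assignments is None:
            key = {r.id: r.sequence.upper() for r in records}
        else:
            key = dict(assignments)
        for i, a in enumerate(records):
            for j in range(i + 1, n):
                d2[i, j] = d2[j, i] = 0.0 if key[a.id] == key[records[j].id] else 1.0
    elif mode == "nt_differences":
        for i, a in enumerate(records):
            for j in range(i + 1, n):
                nd = _pairwise_differences(a.sequence.upper(), records[j].sequence.upper())
                d2[i, j] = d2[j, i] = float(nd) ** 2
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return DistanceMatrix(labels, d2)


@dataclass
class AmovaResult:
    """Degrees of freedom, sums of squares, variance components, Phi statistics."""

    df: dict[str, int]
    ss: dict[str, float]
    variance_components: dict[str, float]  # Va, Vb, Vc
    percentages: dict[str, float]
    phi: dict[str, float | None]  # phi_ct, phi_sc, phi_st (None when undefined)
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None

    @property
    def total_variance(self) -> float:
        return sum(v for v in self.variance_components.values())

    def to_frame(self) -> pd.DataFrame:
        """AMOVA table with the conventional columns."""
        rows = [
            ("Among groups", "among_groups", "Va", "phi_ct"),
            ("Among populations within groups", "among_pops_within_groups", "Vb", "phi_sc"),
            ("Within populations", "within_pops", "Vc", "phi_st"),
        ]
        recs = []
        for source, key, comp, phi_key in rows:
            if key not in self.ss:
                continue
            recs.append(
                {
                    "Source of variation": source,
                    "d.f.": self.df[key],
                    "Sum of squares": self.ss[key],
                    "Variance components": self.variance_components.get(comp),
                    "Percentage of variation": self.percentages.get(comp),
                    "Fixation index": self.phi.get(phi_key),
                    "P": self.p_values.get(phi_key),
                }
            )
        recs.append(
            {
                "Source of variation": "Total",
                "d.f.": self.df["total"],
                "Sum of squares": self.ss["total"],
                "Variance components": self.total_variance,
                "Percentage of variation": 100.0 if self.total_variance > 0 else None,
                "Fixation index": None,
                "P": None,
            }
        )
        return pd.DataFrame.from_records(recs)


def _ss_within(d2: np.ndarray, parts: list[np.ndarray]) -> float:
    """Sum over parts of (pair sum of d2 within the part) / part size."""
    return float(
        sum(d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx)) for idx in parts if len(idx))
    )


def _components(
    d2: np.ndarray, pop_of: np.ndarray, group_of_pop: dict, pops: list
) -> dict:
    """Variance components for one (possibly permuted) assignment.

    ``pop_of`` holds a population index per individual; ``group_of_pop`` maps
    population -> group label for the populations in ``pops``.
    """
    N = d2.shape[0]
    pop_idx = [np.flatnonzero(pop_of == k) for k in range(len(pops))]
    sizes = np.array([len(ix) for ix in pop_idx], dtype=float)
    groups: dict = {}
    for k, p in enumerate(pops):
        groups.setdefault(group_of_pop[p], []).append(k)
    group_idx = [np.concatenate([pop_idx[k] for k in ks]) for ks in groups.values()]
    G, P = len(group_idx), len(pops)

    ss_total = d2.sum() / (2.0 * N)
    ss_wp = _ss_within(d2, pop_idx)
    ss_wg = _ss_within(d2, group_idx)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    df_wp = N - P
    vc = ss_wp / df_wp if df_wp > 0 else 0.0

    out = {
        "N": N,
        "P": P,
        "G": G,
        "ss_total": ss_total,
        "ss_wp": ss_wp,
        "ss_ap": ss_ap,
        "ss_ag": ss_ag,
        "vc": vc,
    }

    if G == 1:
        # single-level design: among populations vs within populations
        df_ap = P - 1
        n0 = (N - float(np.sum(sizes**2)) / N) / df_ap
        vb = (ss_ap / df_ap - vc) / n0 if df_ap > 0 else 0.0
        out.update({"va": 0.0, "vb": vb, "single_level": True})
        return out

    # weighted sample-size coefficients n', n'', n''' of the two-level design
    per_group_sq = []
    group_sizes = []
    for ks in groups.values():
        ng = float(sizes[ks].sum())
        group_sizes.append(ng)
        per_group_sq.append(float(np.sum(sizes[ks] ** 2)) / ng)
    sum_sq_over_group = float(np.sum(per_group_sq))
    n2 = (sum_sq_over_group - float(np.sum(sizes**2)) / N) / (G - 1)
    n3 = (N - float(np.sum(np.array(group_sizes) ** 2)) / N) / (G - 1)

    if P == G:
        # one population per group: no among-populations-within-groups level
        vb = 0.0
    else:
        n1 = (N - sum_sq_over_group) / (P - G)
        vb = (ss_ap / (P - G) - vc) / n1
    ms_ag = ss_ag / (G - 1)
    va = (ms_ag - vc - n2 * vb) / n3
    out.update({"va": va, "vb": vb, "single_level": False})
    return out


def _phi(comp: dict, eps: float = 1e-12) -> dict:
    va, vb, vc = comp["va"], comp["vb"], comp["vc"]
    total = va + vb + vc
    phi: dict[str, float | None] = {"phi_ct": None, "phi_sc": None, "phi_st": None}
    if abs(total) > eps:
        phi["phi_st"] = (va + vb) / total
        if not comp["single_level"]:
            phi["phi_ct"] = va / total
    if abs(vb + vc) > eps:
        phi["phi_sc"] = vb / (vb + vc)
    if comp["single_level"]:
        phi["phi_sc"] = phi["phi_st"]
    return phi


def amova(
    d: DistanceMatrix,
    pop_map: dict[str, str],
    group_map: dict[str, str] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level hierarchical AMOVA on squared distances.

    ``pop_map`` maps record id -> population; ``group_map`` maps population
    -> group (omit it, or map everything to one group, for a single-level
    analysis). With ``n_perm`` > 0, permutation p-values are computed for
    every defined Phi statistic.
    """
    missing = [l for l in d.labels if l not in pop_map]
    if missing:
        raise ValueError(f"records without population assignment: {missing[:5]}")
    pops = sorted({pop_map[l] for l in d.labels})
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if group_map is None:
        group_map = {p: "all" for p in pops}
    missing_g = [p for p in pops if p not in group_map]
    if missing_g:
        raise ValueError(f"populations without group assignment: {missing_g}")
    group_of_pop = {p: group_map[p] for p in pops}

    # canonicalize by label order so results (and permutation streams) do not
    # depend on the order records arrived in
    order = np.argsort(np.array(d.labels, dtype=object))
    labels = [d.labels[i] for i in order]
    pop_index = {p: k for k, p in enumerate(pops)}
    pop_of = np.array([pop_index[pop_map[l]] for l in labels])
    d2 = d.values[np.ix_(order, order)]

    comp = _components(d2, pop_of, group_of_pop, pops)
    N, P, G = comp["N"], comp["P"], comp["G"]
    single = comp["single_level"]
    phi = _phi(comp)

    if single:
        df = {"among_pops_within_groups": P - 1, "within_pops": N - P, "total": N - 1}
        ss = {
            "among_pops_within_groups": comp["ss_ap"],
            "within_pops": comp["ss_wp"],
            "total": comp["ss_total"],
        }
    else:
        df = {
            "among_groups": G - 1,
            "among_pops_within_groups": P - G,
            "within_pops": N - P,
            "total": N - 1,
        }
        ss = {
            "among_groups": comp["ss_ag"],
            "among_pops_within_groups": comp["ss_ap"],
            "within_pops": comp["ss_wp"],
            "total": comp["ss_total"],
        }

    va, vb, vc = comp["va"], comp["vb"], comp["vc"]
    total_var = va + vb + vc
    if abs(total_var) > 1e-12:
        percentages = {
            "Va": 100.0 * va / total_var,
            "Vb": 100.0 * vb / total_var,
            "Vc": 100.0 * vc / total_var,
        }
    else:
        percentages = {"Va": 0.0, "Vb": 0.0, "Vc": 0.0}
    if single:
        variance_components = {"Vb": vb, "Vc": vc}
        percentages.pop("Va")
    else:
        variance_components = {"Va": va, "Vb": vb, "Vc": vc}

    result = AmovaResult(
        df=df,
        ss=ss,
        variance_components=variance_components,
        percentages=percentages,
        phi=phi,
        n_permutations=n_perm,
        seed=seed,
    )
    if n_perm > 0 and any(v is not None for v in phi.values()):
        result.p_values = _permutation_pvalues(
            d2, pop_of, group_of_pop, pops, phi, n_perm, seed
        )
    return result


def _perm_stat(d2, pop_of, group_of_pop, pops, key):
    comp = _components(d2, pop_of, group_of_pop, pops)
    return _phi(comp)[key]


def _permutation_pvalues(
    d2: np.ndarray,
    pop_of: np.ndarray,
    group_of_pop: dict,
    pops: list,
    observed: dict,
    n_perm: int,
    seed: int | None,
) -> dict[str, float]:
    """Inclusive permutation p-values, one scheme per Phi statistic."""
    rng = np.random.default_rng(seed)
    eps = 1e-12
    p_values: dict[str, float] = {}
    group_labels = sorted({group_of_pop[p] for p in pops})
    members = {
        g: [p for p in pops if group_of_pop[p] == g] for g in group_labels
    }

    # Phi_ST: individuals permuted among populations ignoring groups
    if observed["phi_st"] is not None:
        k = 0
        for _ in range(n_perm):
            perm = rng.permutation(pop_of)
            stat = _perm_stat(d2, perm, group_of_pop, pops, "phi_st")
            if stat is not None and stat >= observed["phi_st"] - eps:
                k += 1
        p_values["phi_st"] = (k + 1) / (n_perm + 1)

    # Phi_SC: individuals permuted among populations within their group
    if observed["phi_sc"] is not None and len(group_labels) > 1:
        group_of_ind = np.array(
            [group_labels.index(group_of_pop[pops[p]]) for p in pop_of]
        )
        k = 0
        for _ in range(n_perm):
            perm = pop_of.copy()
            for gi in range(len(group_labels)):
                ix = np.flatnonzero(group_of_ind == gi)
                perm[ix] = perm[ix][rng.permutation(len(ix))]
            stat = _perm_stat(d2, perm, group_of_pop, pops, "phi_sc")
            if stat is not None and stat >= observed["phi_sc"] - eps:
                k += 1
        p_values["phi_sc"] = (k + 1) / (n_perm + 1)

    # Phi_CT: whole populations permuted among groups (group sizes kept)
    if observed["phi_ct"] is not None:
        sizes = [len(members[g]) for g in group_labels]
        k = 0
        for _ in range(n_perm):
            shuffled = list(rng.permutation(pops))
            gmap = {}
            start = 0
            for g, sz in zip(group_labels, sizes):
                for p in shuffled[start : start + sz]:
                    gmap[p] = g
                start += sz
            stat = _perm_stat(d2, pop_of, gmap, pops, "phi_ct")
            if stat is not None and stat >= observed["phi_ct"] - eps:
                k += 1
        p_values["phi_ct"] = (k + 1) / (n_perm + 1)
    return p_values
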