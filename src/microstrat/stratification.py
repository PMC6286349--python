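"""Community steady states, co-abundance groups (CAGs), dietary groups.

Steady states are recurrent whole-community configurations: clusters of
samples whose OTU profiles are mutually rank-correlated.  They are found by
Ward linkage on the Spearman-correlation distance ``(1 - rho) / 2`` between
samples (prevalence-filtered relative OTU abundances), verified by (a) the
per-cluster fraction of intra-cluster sample pairs with a BH-significant
positive correlation and (b) a PERMANOVA of the labels against the same
distance matrix.

CAGs are clusters of genera whose abundance profiles co-vary across samples
(Kendall tau-b associations, Storey q-values, Ward clustering); each CAG is
named after its dominant — most abundant — genus.  Dietary groups are Ward
clusters of the first correspondence-analysis axis of the food-frequency
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .community import AbundanceTable, OtuTable, UNCLASSIFIED, aggregate_taxonomy, alpha_diversity, relative_abundance
from .ordination import PermTestResult, correspondence_analysis, permanova

__all__ = [
    "SteadyStateResult",
    "CagResult",
    "WiggumLayout",
    "DietClusterResult",
    "identify_steady_states",
    "identify_cags",
    "wiggum_overabundance",
    "identify_diet_groups",
    "pairing_statistic",
    "storey_qvalues",
]


def correlation_distance(rho: np.ndarray, kind: str = "signed") -> np.ndarray:
    """Distance from a correlation matrix.

    ``signed``: (1 - rho)/2 maps [-1, 1] -> [1, 0]; ``absolute``: 1 - |rho|.
    """
    if kind == "signed":
        d = (1.0 - rho) / 2.0
    elif kind == "absolute":
        d = 1.0 - np.abs(rho)
    else:
        raise ValueError(f"unknown correlation-distance kind {kind!r}")
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def _ward(dist: np.ndarray, variant: str = "D2") -> np.ndarray:
    """Ward linkage on a precomputed distance matrix.

    ``D2`` (default) applies the Lance-Williams Ward update to the distances
    as given (scipy's ``ward``); ``D`` is the legacy variant operating on
    squared distances with a square-root readout.
    """
    cond = squareform(dist, checks=False)
    if variant == "D2":
        return linkage(cond, method="ward")
    if variant == "D":
        Z = linkage(cond ** 2, method="ward")
        Z = Z.copy()
        Z[:, 2] = np.sqrt(Z[:, 2])
        return Z
    raise ValueError(f"unknown Ward variant {variant!r}")


def _cut(Z: np.ndarray, dist: np.ndarray, k, k_range=range(2, 9)) -> tuple[np.ndarray, int]:
    """Cut a linkage at k clusters; k='auto' maximises mean silhouette."""
    if k == "auto":
        best_k, best_s = None, -np.inf
        n = dist.shape[0]
        for kk in k_range:
            if kk >= n:
                break
            lab = fcluster(Z, kk, criterion="maxclust")
            if np.unique(lab).size < 2:
                continue
            s = silhouette_score(dist, lab, metric="precomputed")
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        if best_k is None:
            raise ValueError("silhouette-based cluster selection failed")
        k = best_k
    labels = fcluster(Z, int(k), criterion="maxclust")
    return labels, int(np.unique(labels).size)


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Spearman correlation between the rows of X (ties mid-ranked)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    return np.corrcoef(ranks)


@dataclass
class SteadyStateResult:
    labels: pd.Series                   # sample -> "C1".."Ck"
    k: int
    linkage: np.ndarray
    distance: DistanceMatrix            # Spearman-based sample distance
    verification: pd.DataFrame          # per-cluster intra-pair significance
    permanova_result: PermTestResult
    n_otus_retained: int


def identify_steady_states(
    table: OtuTable,
    prevalence_min: float = 0.20,
    k="auto",
    distance_kind: str = "signed",
    ward_variant: str = "D2",
    permutations: int = 999,
    seed: int | None = None,
    fdr: float = 0.05,
) -> SteadyStateResult:
    """Stratify samples into microbiota steady states C1..Ck.

    OTUs are filtered to those present in at least ``prevalence_min`` of the
    samples; steady states are Ward clusters of the inter-sample Spearman
    correlation distance of the remaining relative abundances.  Clusters are
    renamed C1..Ck by *descending* mean Shannon diversity, so C1 is the most
    diverse state and Ck the least.
    """
    if table.counts.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    rel = relative_abundance(table).values
    prevalence = (rel > 0).mean(axis=0)
    keep = rel.columns[prevalence >= prevalence_min]
    if keep.empty:
        raise ValueError(
            f"prevalence filter ({prevalence_min:.0%}) removed every OTU"
        )
    X = rel[keep].to_numpy(dtype=float)
    rho = spearman_matrix(X)
    dist = correlation_distance(rho, kind=distance_kind)
    Z = _ward(dist, variant=ward_variant)
    raw_labels, k_used = _cut(Z, dist, k)
    # rename clusters by descending mean Shannon diversity
    sh = alpha_diversity(table, "shannon")
    order = (
        pd.Series(sh.to_numpy(), index=raw_labels)
        .groupby(level=0).mean().sort_values(ascending=False).index
    )
    name_of = {c: f"C{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([name_of[c] for c in raw_labels], index=table.counts.index, name="state")

    # verification (a): intra-cluster positive-correlation significance with BH
    n_feat = X.shape[1]
    pairs, pvals, rhos = [], [], []
    lab_arr = labels.to_numpy()
    for c in sorted(set(lab_arr)):
        idx = np.flatnonzero(lab_arr == c)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                r = rho[idx[a], idx[b]]
                # t approximation for Spearman's rho
                r_ = np.clip(r, -0.999999, 0.999999)
                t = r_ * np.sqrt((n_feat - 2) / (1 - r_ ** 2))
                p = 2 * stats.t.sf(abs(t), df=n_feat - 2)
                pairs.append(c)
                rhos.append(r)
                pvals.append(p)
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        sig_pos = (adj <= fdr) & (np.asarray(rhos) > 0)
        ver = (
            pd.DataFrame({"cluster": pairs, "significant_positive": sig_pos})
            .groupby("cluster")["significant_positive"]
            .agg(n_pairs="size", fraction_significant="mean")
            .reset_index()
        )
    else:
        ver = pd.DataFrame(columns=["cluster", "n_pairs", "fraction_significant"])

    dm = DistanceMatrix(dist, ids=[str(s) for s in table.counts.index])
    perm = permanova(dm, lab_arr, permutations=permutations, seed=seed)
    return SteadyStateResult(
        labels=labels, k=k_used, linkage=Z, distance=dm,
        verification=ver, permanova_result=perm, n_otus_retained=int(len(keep)),
    )


def storey_qvalues(pvalues, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed lambda.

    ``pi0 = #{p > lambda} / ((1 - lambda) m)`` capped at 1; q-values are the
    step-up minimum of ``pi0 * m * p_(i) / i`` from the largest p downwards.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    pi0 = min(1.0, (p > lam).sum() / ((1.0 - lam) * m))
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank)
        q[i] = val
        prev = val
    return q


@dataclass
class CagResult:
    labels: pd.Series                  # genus -> "CAG1".."CAGk"
    k: int
    tau: pd.DataFrame                  # Kendall tau-b between genera
    qvalues: pd.DataFrame
    edges: pd.DataFrame                # genus_a, genus_b, tau_b, q, sign
    dominant: dict                     # CAG label -> dominant genus
    linkage: np.ndarray
    mean_abundance: pd.Series          # cohort mean relative abundance


def identify_cags(
    table: OtuTable,
    min_abundance: float = 0.001,
    min_samples: int = 2,
    fdr: float = 0.05,
    k="auto",
    distance_kind: str = "signed",
    cluster_on: str = "spearman",
    ward_variant: str = "D2",
    qvalue_method: str = "storey",
    include_unclassified: bool = False,
) -> CagResult:
    """Cluster genera into co-abundance groups.

    Genera exceeding ``min_abundance`` relative abundance in at least
    ``min_samples`` samples are tested pairwise with Kendall's tau-b;
    significance is controlled at ``fdr`` with Storey q-values (BH behind
    ``qvalue_method='bh'``).  Clustering is Ward on the Spearman correlation
    distance between genus profiles (``cluster_on='kendall'`` uses the tau
    matrix instead).  CAG labels are ordered by descending total mean
    abundance; each CAG's dominant genus is its most abundant member.
    """
    genus = relative_abundance(aggregate_taxonomy(table, "genus"))
    vals = genus.values
    if not include_unclassified and UNCLASSIFIED in vals.columns:
        vals = vals.drop(columns=[UNCLASSIFIED])
    keep = vals.columns[((vals > min_abundance).sum(axis=0) >= min_samples)]
    if len(keep) < 5:
        raise ValueError(
            f"only {len(keep)} genera retained (need >= 5); filter: "
            f"abundance > {min_abundance}, in >= {min_samples} samples, "
            f"from {vals.shape[1]} candidate genera"
        )
    X = vals[keep].to_numpy(dtype=float).T  # genera x samples
    g = X.shape[0]
    tau = np.eye(g)
    pmat = np.zeros((g, g))
    pairs = []
    for i in range(g):
        for j in range(i + 1, g):
            t, p = stats.kendalltau(X[i], X[j], variant="b")
            if np.isnan(t):
                t, p = 0.0, 1.0
            tau[i, j] = tau[j, i] = t
            pmat[i, j] = pmat[j, i] = p
            pairs.append((i, j, t, p))
    pvals = np.array([p for *_, p in pairs])
    if qvalue_method == "storey":
        qvals = storey_qvalues(pvals)
    elif qvalue_method == "bh":
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown q-value method {qvalue_method!r}")
    qmat = np.eye(g) * 0.0
    edges = []
    for (i, j, t, p), q in zip(pairs, qvals):
        qmat[i, j] = qmat[j, i] = q
        if q <= fdr:
            edges.append((keep[i], keep[j], t, q, int(np.sign(t))))
    edges_df = pd.DataFrame(edges, columns=["genus_a", "genus_b", "tau_b", "q", "sign"])

    if cluster_on == "spearman":
        rho = spearman_matrix(X)
        dist = correlation_distance(rho, kind=distance_kind)
    elif cluster_on == "kendall":
        dist = correlation_distance(tau, kind=distance_kind)
    else:
        raise ValueError(f"unknown cluster_on {cluster_on!r}")
    Z = _ward(dist, variant=ward_variant)
    raw_labels, k_used = _cut(Z, dist, k)

    mean_ab = vals[keep].mean(axis=0)
    # order CAGs by descending summed mean abundance
    totals = pd.Series(mean_ab.to_numpy(), index=raw_labels).groupby(level=0).sum()
    order = totals.sort_values(ascending=False).index
    name_of = {c: f"CAG{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([name_of[c] for c in raw_labels], index=keep, name="cag")
    dominant = {
        cag: mean_ab[labels[labels == cag].index].idxmax()
        for cag in sorted(labels.unique(), key=lambda s: int(s[3:]))
    }
    return CagResult(
        labels=labels, k=k_used,
        tau=pd.DataFrame(tau, index=keep, columns=keep),
        qvalues=pd.DataFrame(qmat, index=keep, columns=keep),
        edges=edges_df, dominant=dominant, linkage=Z, mean_abundance=mean_ab,
    )


@dataclass
class WiggumLayout:
    """Per-(steady state, genus) over-abundance ratios plus the CAG network."""

    ratios: pd.DataFrame       # states x genera, cluster mean / cohort mean
    node_sizes: pd.Series      # cohort mean relative abundance per genus
    cags: pd.Series            # genus -> CAG label
    edges: pd.DataFrame


def wiggum_overabundance(
    table: OtuTable,
    states: SteadyStateResult,
    cags: CagResult,
) -> WiggumLayout:
    """Genus over-abundance per steady state relative to the cohort mean."""
    genus = relative_abundance(aggregate_taxonomy(table, "genus")).values
    genera = [g for g in cags.labels.index if g in genus.columns]
    cohort_mean = genus[genera].mean(axis=0)
    dead = cohort_mean.index[cohort_mean == 0]
    if len(dead):
        warnings.warn(f"genera absent cohort-wide excluded: {list(dead)}", UserWarning, stacklevel=2)
        genera = [g for g in genera if g not in set(dead)]
        cohort_mean = cohort_mean.drop(index=dead)
    lab = states.labels.loc[genus.index]
    cluster_mean = genus[genera].groupby(lab).mean()
    ratios = cluster_mean.div(cohort_mean, axis=1)
    return WiggumLayout(
        ratios=ratios,
        node_sizes=cohort_mean,
        cags=cags.labels.loc[genera],
        edges=cags.edges,
    )


@dataclass
class DietClusterResult:
    labels: pd.Series            # sample -> "D1".."Dm"
    m: int
    axis1_scores: pd.Series
    linkage: np.ndarray
    ca_proportion_axis1: float


def identify_diet_groups(
    ffq_values: pd.DataFrame,
    m=5,
    ward_variant: str = "D2",
) -> DietClusterResult:
    """Dietary groups D1..Dm from the first correspondence-analysis axis.

    The samples x foods consumption matrix is ordinated by CA; Ward linkage
    with Euclidean distance on the axis-1 row scores is cut at ``m`` groups
    (``m='auto'`` selects 2..8 by silhouette).  Groups are renamed D1..Dm by
    ascending within-group mean axis-1 score.
    """
    F = pd.DataFrame(ffq_values).astype(float)
    ca = correspondence_analysis(F)
    if ca.eigenvalues.size == 0 or ca.eigenvalues[0] <= 0:
        raise ValueError("degenerate correspondence analysis (zero inertia)")
    scores = ca.coordinates.iloc[:, 0]
    x = scores.to_numpy()[:, None]
    dist = np.abs(x - x.T)
    if ward_variant == "D2":
        Z = linkage(x, method="ward")
    else:
        Z = _ward(dist, variant=ward_variant)
    raw_labels, m_used = _cut(Z, dist, m)
    means = pd.Series(scores.to_numpy(), index=raw_labels).groupby(level=0).mean()
    order = means.sort_values(ascending=True).index
    name_of = {c: f"D{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([name_of[c] for c in raw_labels], index=F.index, name="diet_group")
    scores.index = F.index
    return DietClusterResult(
        labels=labels, m=m_used, axis1_scores=scores, linkage=Z,
        ca_proportion_axis1=float(ca.proportion_explained[0]),
    )


def pairing_statistic(
    distance: DistanceMatrix | np.ndarray,
    subject_map: pd.Series,
    permutations: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Within-subject sample pairing in a distance matrix.

    The statistic is the number of subjects whose two samples are mutual
    nearest neighbours.  The null permutes the subject assignment of the
    samples; the p-value uses the +1 convention.
    """
    if isinstance(distance, DistanceMatrix):
        D = distance.data
        ids = list(distance.ids)
    else:
        D = np.asarray(distance, dtype=float)
        ids = list(range(D.shape[0]))
    subject_map = pd.Series(subject_map)
    sizes = subject_map.value_counts()
    bad = sizes.index[sizes != 2]
    if len(bad):
        raise ValueError(f"subjects without exactly 2 samples: {list(bad)[:5]}")
    pos = {str(s): i for i, s in enumerate(ids)}
    subj_arr = np.empty(D.shape[0], dtype=object)
    for s, subj in subject_map.items():
        subj_arr[pos[str(s)]] = subj
    Dm = D.copy()
    np.fill_diagonal(Dm, np.inf)
    nn = Dm.argmin(axis=1)

    def count_mutual(assign: np.ndarray) -> int:
        c = 0
        groups: dict = {}
        for i, s in enumerate(assign):
            groups.setdefault(s, []).append(i)
        for a, b in groups.values():
            if nn[a] == b and nn[b] == a:
                c += 1
        return c

    obs = count_mutual(subj_arr)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if count_mutual(rng.permutation(subj_arr)) >= obs:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return PermTestResult(statistic=float(obs), permutations=permutations, p_value=p, name="mutual-NN pairs")
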