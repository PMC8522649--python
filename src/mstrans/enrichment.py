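"""Differential expression screening, overlap tests, cell-type specificity.

Implements the downstream gene-set machinery: empirical-Bayes moderated
two-group differential expression, hypergeometric/Fisher overlap with
Bonferroni correction, a permutation-calibrated specificity index (pSI) for
cell-type-enriched gene lists, and generic over-representation against
arbitrary gene-set collections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from mstrans.transcription import GeneSet

logger = logging.getLogger(__name__)

EPS = 1e-9


# ---------------------------------------------------------------------------
# moderated differential expression


@dataclass
class DEResult:
    """Per-gene moderated two-group statistics and threshold labels."""

    table: pd.DataFrame  # columns: log2fc, t_mod, p, label
    d0: float
    s0_sq: float
    p_thresh: float
    fc_thresh: float

    @property
    def up(self) -> GeneSet:
        sel = self.table.index[self.table["label"] == "up"]
        return GeneSet("DEG_up", tuple(map(str, sel)))

    @property
    def down(self) -> GeneSet:
        sel = self.table.index[self.table["label"] == "down"]
        return GeneSet("DEG_down", tuple(map(str, sel)))


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < tol:
            break
    return y


def fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to sample variances.

    Returns (d0, s0_sq): prior degrees of freedom and prior variance such
    that s2 ~ s0_sq * F(df1, d0), estimated on the log scale via
    digamma/trigamma moments.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.all():
        s2 = np.where(ok, s2, s2[ok].min())
    z = np.log(s2)
    e = z - float(special.digamma(df1 / 2)) + math.log(df1 / 2)
    n = z.size
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (n - 1) - float(
        special.polygamma(1, df1 / 2)
    )
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def moderated_de(
    expr: pd.DataFrame,
    groups: pd.Series,
    p_thresh: float = 0.01,
    fc_thresh: float = 1.0,
    d0_override: float | None = None,
) -> DEResult:
    """Two-group moderated differential expression on log2-scale data.

    Per gene, the pooled two-group variance is shrunk toward a moment-matched
    prior: s~2 = (d0*s0^2 + dg*s2) / (d0 + dg); the moderated t uses dg + d0
    degrees of freedom. ``d0_override=0`` recovers the ordinary per-gene
    pooled t. Labels: up if p < p_thresh and log2fc > fc_thresh; down if
    p < p_thresh and log2fc < -fc_thresh; ns otherwise.

    Parameters
    ----------
    expr
        Samples x genes matrix of log2 expression.
    groups
        Per-sample labels, aligned to ``expr`` rows; exactly two levels, with
        'case'/'control' ordered as (case - control) if present, else the
        two levels in sorted order (second minus first).
    """
    groups = groups.astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if "case" in levels and "control" in levels:
        g_case, g_ctrl = "case", "control"
    else:
        g_ctrl, g_case = levels
    a = expr.loc[groups.to_numpy() == g_case].to_numpy(dtype=float)
    b = expr.loc[groups.to_numpy() == g_ctrl].to_numpy(dtype=float)
    n1, n2 = a.shape[0], b.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("need >=2 samples per group")
    lfc = a.mean(axis=0) - b.mean(axis=0)
    dg = n1 + n2 - 2
    s2 = ((a - a.mean(axis=0)) ** 2).sum(axis=0)
    s2 += ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    s2 /= dg
    if np.any(s2 == 0):
        bad = expr.columns[s2 == 0][:10].tolist()
        raise ValueError(f"zero variance in both groups for genes {bad}")

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_f_dist(s2, dg)
    else:
        d0, s0_sq = fit_f_dist(s2, dg)

    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = dg + d0
    se = np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
    t_mod = lfc / se
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    label = np.where(
        (p < p_thresh) & (lfc > fc_thresh),
        "up",
        np.where((p < p_thresh) & (lfc < -fc_thresh), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": lfc, "t_mod": t_mod, "p": p, "label": label},
        index=pd.Index(expr.columns, name="gene"),
    )
    return DEResult(
        table=table, d0=d0, s0_sq=s0_sq, p_thresh=p_thresh, fc_thresh=fc_thresh
    )


# ---------------------------------------------------------------------------
# overlap testing


@dataclass
class OverlapResult:
    """2x2 enrichment statistics for two gene sets over a background."""

    label_a: str
    label_b: str
    k: int
    nA: int
    nB: int
    N: int
    odds_ratio: float
    p: float  # p at the chosen sidedness
    pc: float  # Bonferroni-corrected
    p_one_sided: float
    p_two_sided: float
    m_comparisons: int
    alternative: str

    @property
    def gene_ratio(self) -> float:
        return self.k / self.nB if self.nB else 0.0

    @property
    def background_fraction(self) -> float:
        return self.k / self.N


def fisher_overlap(
    set_a: GeneSet,
    set_b: GeneSet,
    background: set | tuple | list,
    m_comparisons: int = 1,
    alternative: str = "greater",
) -> OverlapResult:
    """Significance of the overlap of two gene sets within a background.

    One-sided ('greater') is the hypergeometric upper tail
    P(X >= k | N, nA, nB); 'two-sided' is Fisher's exact test. The Bonferroni
    correction is pc = min(1, m_comparisons * p).
    """
    bg = set(map(str, background))
    a = set(map(str, set_a.genes))
    b = set(map(str, set_b.genes))
    stray = sorted((a | b) - bg)
    if stray:
        raise ValueError(f"genes outside background: {stray[:10]}")
    return overlap_from_counts(
        k=len(a & b),
        nA=len(a),
        nB=len(b),
        N=len(bg),
        m_comparisons=m_comparisons,
        alternative=alternative,
        label_a=set_a.label,
        label_b=set_b.label,
    )


def overlap_from_counts(
    k: int,
    nA: int,
    nB: int,
    N: int,
    m_comparisons: int = 1,
    alternative: str = "greater",
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapResult:
    """Overlap test from the four counts of the 2x2 table."""
    if not (0 <= k <= min(nA, nB)) or max(nA, nB) > N:
        raise ValueError("inconsistent contingency counts")
    table = np.array([[k, nA - k], [nB - k, N - nA - nB + k]])
    p_one = float(stats.hypergeom.sf(k - 1, N, nA, nB))
    _, p_two = stats.fisher_exact(table, alternative="two-sided")
    denom = (nA - k) * (nB - k)
    odds = (k * (N - nA - nB + k) / denom) if denom else math.inf
    if alternative == "greater":
        p = p_one
    elif alternative == "two-sided":
        p = float(p_two)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return OverlapResult(
        label_a=label_a,
        label_b=label_b,
        k=k,
        nA=nA,
        nB=nB,
        N=N,
        odds_ratio=float(odds),
        p=p,
        pc=min(1.0, m_comparisons * p),
        p_one_sided=p_one,
        p_two_sided=float(p_two),
        m_comparisons=m_comparisons,
        alternative=alternative,
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return float(f"%.{sig}g" % x)


def overlap_summary(res: OverlapResult) -> dict:
    """Display-ready ratios: background %, 1 decimal; gene ratio, 2 sig figs."""
    return {
        "overlap": res.k,
        "set_a": res.nA,
        "set_b": res.nB,
        "background": res.N,
        "background_percent": round(100 * res.background_fraction, 1),
        "gene_ratio": round_sig(res.gene_ratio, 2),
        "odds_ratio": res.odds_ratio,
        "p": res.p,
        "pc": res.pc,
    }


# ---------------------------------------------------------------------------
# cell-type specificity (pSI)


@dataclass
class PSITable:
    """Specificity-index ranks and permutation p-values per gene per type."""

    si: pd.DataFrame  # genes x types, mean rank of fold change
    psi: pd.DataFrame  # genes x types, permutation p in (0, 1]
    enriched: dict  # type -> GeneSet at the configured threshold
    psi_thresh: float
    B_perm: int


def psi_compute(
    profile: pd.DataFrame,
    B_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    psi_thresh: float = 0.05,
    eps: float = EPS,
) -> PSITable:
    """Specificity index with permutation calibration.

    For target type c and gene g, the fold change of g's expression in c over
    each other type is ranked descending across genes (average ranks on
    ties); si is the mean rank over the comparisons. The null permutes each
    cell-type column's expression values independently across genes and
    recomputes si, which preserves the dependence between comparisons induced
    by the shared numerator; psi = (1 + #{null si <= observed}) /
    (1 + B_perm). Genes with psi < ``psi_thresh`` form each type's enriched
    list.
    """
    if profile.shape[1] < 2:
        raise ValueError("need >=2 cell types")
    if profile.shape[0] < 2:
        raise ValueError("need >=2 genes")
    if (profile.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    if B_perm < 100:
        logger.warning("B_perm=%d < 100: psi resolution is coarse", B_perm)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = profile.to_numpy(dtype=float) + eps
    genes, types = profile.index, list(profile.columns)
    G, T = x.shape
    si = np.empty((G, T))
    psi = np.empty((G, T))
    # one independent gene-permutation per column per null iteration
    perm = np.empty((T, B_perm, G), dtype=np.intp)
    base = np.tile(np.arange(G), (B_perm, 1))
    for t in range(T):
        perm[t] = rng.permuted(base, axis=1)
    for c in range(T):
        others = [t for t in range(T) if t != c]
        ranks = np.empty((T - 1, G))
        null = np.zeros((B_perm, G))
        xc_null = x[perm[c], c]  # shared numerator across comparisons
        for j, d in enumerate(others):
            fc = x[:, c] / x[:, d]
            ranks[j] = stats.rankdata(-fc, method="average")
            null += stats.rankdata(
                -xc_null / x[perm[d], d], method="average", axis=1
            )
        si[:, c] = ranks.mean(axis=0)
        null /= T - 1
        psi[:, c] = (1 + (null <= si[:, c][None, :]).sum(axis=0)) / (
            1 + B_perm
        )
    si_df = pd.DataFrame(si, index=genes, columns=types)
    psi_df = pd.DataFrame(psi, index=genes, columns=types)
    enriched = {
        t: GeneSet(
            str(t), tuple(map(str, psi_df.index[psi_df[t] < psi_thresh]))
        )
        for t in types
    }
    return PSITable(
        si=si_df,
        psi=psi_df,
        enriched=enriched,
        psi_thresh=psi_thresh,
        B_perm=B_perm,
    )


# ---------------------------------------------------------------------------
# generic over-representation


def ora_collection(
    query: GeneSet,
    collection: dict,
    background: set | tuple | list,
    m_comparisons: int | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher overlap of a query set against every set of a collection.

    Bonferroni correction defaults to the collection size. Returns a tidy
    table sorted by corrected p.
    """
    if not collection:
        raise ValueError("empty collection")
    m = m_comparisons if m_comparisons is not None else len(collection)
    rows = []
    for name, gs in collection.items():
        res = fisher_overlap(
            query, gs, background, m_comparisons=m, alternative=alternative
        )
        rows.append(
            {
                "set": name,
                "k": res.k,
                "n_query": res.nA,
                "n_set": res.nB,
                "N": res.N,
                "gene_ratio": res.gene_ratio,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
                "pc": res.pc,
            }
        )
    return (
        pd.DataFrame(rows).sort_values(["pc", "p"]).reset_index(drop=True)
    )
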