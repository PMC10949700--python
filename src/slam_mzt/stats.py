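"""Differential tests on count fractions, masked-decay calling, shift tests.

Fold changes and significance come from a two-group negative-binomial
exact-style test: library sizes are equalised to their geometric mean,
per-gene dispersions are moment-estimated and shrunk toward a common value,
and the p-value is the conditional two-sided tail of the observed group
split given the group-sum total (each group sum being NB with size scaled
by its replicate number).  BH adjustment is applied per comparison and
fraction.  Downstream logic consumes threshold crossings (padj <= 0.2 for
trajectories, <= 0.05 for masked decay), not the exact numerics of any
particular GLM fitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT_CPM = 0.5
DISPERSION_PRIOR_WEIGHT = 20.0


@dataclass
class GroupShiftResult:
    group_a: str
    n_a: int
    group_b: str
    n_b: int
    statistic: float
    pvalue: float
    test: str  # {ks, wilcoxon, chisq}
    alternative: str = "two-sided"
    correction: str = "none"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _moment_dispersions(y: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Per-gene raw moment dispersions (pooled within groups) and the common value."""
    n_genes = y.shape[0]
    num = np.zeros(n_genes)
    df = 0
    means = np.zeros(n_genes)
    n_tot = 0
    for idx in groups:
        sub = y[:, idx]
        if sub.shape[1] >= 2:
            num += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            df += sub.shape[1] - 1
        means += sub.sum(axis=1)
        n_tot += sub.shape[1]
    m = means / n_tot
    s2 = num / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-9) ** 2, np.nan)
    # the per-gene moment estimate is right-skewed, so its median is biased
    # low; the plain mean is the unbiased pooled estimator (clipped against
    # pathological outliers)
    informative = phi[(m > 5) & ~np.isnan(phi)]
    common = float(np.clip(informative, -1.0, 10.0).mean()) if informative.size else 0.0
    common = max(common, 0.0)
    return phi, common


def _exact_nb_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional tail probability of the observed group split.

    Under the null both groups share a per-sample mean mu = total/(n_a+n_b);
    the group sums are NB(size=n/phi, mean=n*mu).  The p-value sums the
    joint probabilities of all splits no more likely than the observed one.
    """
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    k = np.arange(total + 1)
    if phi <= 1e-12:
        la = sps.poisson.logpmf(k, n_a * mu)
        lb = sps.poisson.logpmf(total - k, n_b * mu)
    else:
        size_a, size_b = n_a / phi, n_b / phi
        pnb = 1.0 / (1.0 + mu * phi)  # scipy's p parameter, same for both groups
        la = sps.nbinom.logpmf(k, size_a, pnb)
        lb = sps.nbinom.logpmf(total - k, size_b, pnb)
    logjoint = la + lb
    logjoint -= logjoint.max()
    joint = np.exp(logjoint)
    obs = joint[sum_a]
    return float(min(1.0, joint[joint <= obs * (1 + 1e-10)].sum() / joint.sum()))


def nb_fold_change_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    lib_a,
    lib_b,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
    comparison: str = "a_vs_b",
    fraction: str = "total",
    dispersion: float | None = None,
    max_exact_total: int = 500_000,
) -> pd.DataFrame:
    """Per-gene fold change and NB exact-style p-value between two groups.

    ``counts_a``/``counts_b`` are gene x sample raw counts with a shared
    gene index; ``lib_a``/``lib_b`` are the matching effective library
    sizes (from the total fraction for every fraction).  log2fc is computed
    on mean CPMs with a pseudocount; positive log2fc means higher in group
    a.  Returns gene_id, comparison, fraction, log2fc, pvalue, padj (BH).
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("gene indexes of the two groups must match")
    lib_a = np.asarray(lib_a, dtype=float)
    lib_b = np.asarray(lib_b, dtype=float)
    if lib_a.sum() <= 0 or lib_b.sum() <= 0:
        raise ValueError("a group has all-zero library sizes")

    cpm_a = counts_a.to_numpy(dtype=float) / lib_a[None, :] * 1e6
    cpm_b = counts_b.to_numpy(dtype=float) / lib_b[None, :] * 1e6
    log2fc = np.log2((cpm_a.mean(axis=1) + pseudocount) / (cpm_b.mean(axis=1) + pseudocount))

    # equalise library sizes: pseudo-counts on the geometric-mean library
    libs = np.concatenate([lib_a, lib_b])
    lbar = np.exp(np.log(libs).mean())
    ya = np.rint(counts_a.to_numpy(dtype=float) * (lbar / lib_a)[None, :]).astype(np.int64)
    yb = np.rint(counts_b.to_numpy(dtype=float) * (lbar / lib_b)[None, :]).astype(np.int64)
    y = np.concatenate([ya, yb], axis=1)
    n_a, n_b = ya.shape[1], yb.shape[1]
    groups = [np.arange(n_a), np.arange(n_a, n_a + n_b)]

    if dispersion is not None:
        phi_tag = np.full(y.shape[0], float(dispersion))
    else:
        phi_raw, common = _moment_dispersions(y, groups)
        df_g = max(n_a - 1, 0) + max(n_b - 1, 0)
        phi_raw = np.where(np.isnan(phi_raw), common, phi_raw)
        phi_tag = (DISPERSION_PRIOR_WEIGHT * common + df_g * phi_raw) / (
            DISPERSION_PRIOR_WEIGHT + df_g
        )
        phi_tag = np.clip(phi_tag, 0.0, 10.0)

    pvals = np.empty(y.shape[0])
    for g in range(y.shape[0]):
        sa, sb = int(ya[g].sum()), int(yb[g].sum())
        if sa + sb > max_exact_total:
            # deep-count fallback: normal approximation on the split
            mu = (sa + sb) / (n_a + n_b)
            var_a = n_a * (mu + phi_tag[g] * mu**2)
            var_b = n_b * (mu + phi_tag[g] * mu**2)
            zstat = (sa - n_a * mu) / np.sqrt(var_a * (var_b / (var_a + var_b)) + 1e-12)
            pvals[g] = 2 * sps.norm.sf(abs(zstat))
        else:
            pvals[g] = _exact_nb_pvalue(sa, sb, n_a, n_b, float(phi_tag[g]))

    return pd.DataFrame(
        {
            "gene_id": counts_a.index,
            "comparison": comparison,
            "fraction": fraction,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        }
    ).set_index("gene_id")


def masked_decay_genes(
    de_total_7v2: pd.DataFrame,
    de_total_vs_unlabeled_7h: pd.DataFrame,
    classes: pd.Series,
    has_site: pd.Series,
    known_targets: set[str] | frozenset = frozenset(),
    total_fc_floor: float = -1.5,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag maternal-zygotic genes whose maternal decay is masked by synthesis.

    A gene is masked-decay iff it is maternal_zygotic, not a known miR-430
    target, shows no strong total-mRNA decay between 2 and 7 h
    (total log2FC(7 v 2) > ``total_fc_floor``), yet total vs unlabeled mRNA
    at 7 h drops significantly (padj <= 0.05 and log2FC < 0; the unlabeled
    = maternal fraction has fallen below the total).  The flagged set is
    split by miR-430 site presence into targets vs non-targets.
    """
    for name, df in (("de_total_7v2", de_total_7v2), ("de_total_vs_unlabeled", de_total_vs_unlabeled_7h)):
        if df is None or df.empty:
            raise ValueError(f"missing DE input: {name}")
    genes = de_total_7v2.index.intersection(de_total_vs_unlabeled_7h.index)
    out = pd.DataFrame(index=genes)
    out["mzt_class"] = classes.reindex(genes)
    out["has_site"] = has_site.reindex(genes).fillna(False).astype(bool)
    out["total_log2fc_7v2"] = de_total_7v2.loc[genes, "log2fc"]
    tvu = de_total_vs_unlabeled_7h.loc[genes]
    # total vs unlabeled at 7h: unlabeled below total means maternal loss;
    # the contrast is run as unlabeled vs total, so decay shows as log2fc < 0
    out["tvu_log2fc"] = tvu["log2fc"]
    out["tvu_padj"] = tvu["padj"]
    out["masked_decay"] = (
        (out["mzt_class"] == "maternal_zygotic")
        & ~out.index.isin(list(known_targets))
        & (out["total_log2fc_7v2"] > total_fc_floor)
        & (out["tvu_padj"] <= padj_threshold)
        & (out["tvu_log2fc"] < 0)
    )
    out["group"] = np.where(
        out["masked_decay"] & out["has_site"],
        "masked_decay_target",
        np.where(out["masked_decay"], "masked_decay_nontarget", ""),
    )
    return out


def group_shift(
    values_a,
    values_b,
    test: str = "ks",
    alternative: str = "two-sided",
    correction: str = "none",
    n_comparisons: int = 1,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupShiftResult:
    """One- or two-sided KS / Wilcoxon rank-sum / chi-square comparison.

    For ``ks`` and ``wilcoxon`` with ``alternative="greater"`` the
    alternative hypothesis is that group a's values are shifted toward
    larger values than group b's.  For ``chisq``, ``values_a``/``values_b``
    are category count vectors forming a 2 x k contingency table.
    Degenerate constant inputs give p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")

    if test != "chisq" and np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("degenerate constant inputs; p set to 1", stacklevel=2)
        stat, p = 0.0, 1.0
    elif test == "ks":
        # scipy's 'less' alternative: CDF(a) < CDF(b), i.e. a stochastically larger
        alt = {"greater": "less", "less": "greater"}.get(alternative, "two-sided")
        res = sps.ks_2samp(a, b, alternative=alt)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        res = sps.mannwhitneyu(a, b, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "chisq":
        table = np.vstack([a, b])
        keep = table.sum(axis=0) > 0
        res = sps.chi2_contingency(table[:, keep])
        stat, p = float(res[0]), float(res[1])
    else:
        raise ValueError(f"unknown test {test!r}")

    if correction == "bonferroni":
        p = min(1.0, p * n_comparisons)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return GroupShiftResult(label_a, a.size, label_b, b.size, stat, p, test, alternative, correction)


def lna_derepression(
    de_by_fraction: dict[str, pd.DataFrame],
    targets: set[str],
    controls: set[str],
    control_labeled_cpm: pd.Series | None = None,
    min_labeled_cpm: float = 2.0,
) -> dict[str, GroupShiftResult]:
    """Test miR-430 target de-repression after LNA knockdown, per fraction.

    For each mRNA fraction's LNA-vs-control fold changes, targets (filtered
    to > ``min_labeled_cpm`` labeled CPM in control embryos when
    ``control_labeled_cpm`` is given) are compared to expression-matched
    non-target controls with a one-sided KS test, alternative: target fold
    changes shifted positive (de-repressed without miR-430).
    """
    if control_labeled_cpm is not None:
        targets = {g for g in targets if control_labeled_cpm.get(g, 0.0) > min_labeled_cpm}
    results: dict[str, GroupShiftResult] = {}
    for fraction, de in de_by_fraction.items():
        t_idx = de.index.intersection(list(targets))
        c_idx = de.index.intersection(list(controls))
        if len(t_idx) == 0:
            warnings.warn(f"{fraction}: empty target set after filtering; skipped", stacklevel=2)
            continue
        results[fraction] = group_shift(
            de.loc[t_idx, "log2fc"],
            de.loc[c_idx, "log2fc"],
            test="ks",
            alternative="greater",
            label_a=f"targets_{fraction}",
            label_b=f"controls_{fraction}",
        )
    return results
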