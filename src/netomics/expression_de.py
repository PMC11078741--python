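"""RNA-seq stage: TMM/CPM normalization, NB differential expression with
serial filtering, and the small qPCR validation computations.

The differential-expression contract is the serial-filter semantics: a gene
is called DE iff it survives, in order, the expression filter (CPM > 1 in a
quorum of samples), a nominal test (p < 0.05), an effect-size gate
(|log2FC| >= 1) and Benjamini-Hochberg control (q <= 0.20, computed over the
survivors of the earlier gates by default). The test engine is a
negative-binomial log-linear model with library-size offsets, genewise
moment dispersions shrunk toward the common value, and a likelihood-ratio
test on the contrast coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .types import CountsExperiment, ValidationError

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationFactors:
    """Per-sample library size, TMM scaling factor and effective size."""

    library_size: pd.Series
    tmm: pd.Series

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm


def tmm_factors(exp: CountsExperiment, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions (ties: first in sample order).
    For each sample, M- and A-values over genes expressed in both sample
    and reference are doubly trimmed (``trim_m`` per tail on M, ``trim_a``
    per tail on A) and averaged with asymptotic precision weights; factors
    are rescaled to geometric mean 1.
    """
    counts = exp.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        s = exp.samples[int(np.argmin(lib))]
        raise ValidationError(f"sample {s!r} has zero library size")
    f75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(counts.shape[1])]) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    nr = counts[:, ref]
    Nr = lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ns = counts[:, j]
        Ns = lib[j]
        both = (ns > 0) & (nr > 0)
        if not both.any():
            log.warning("sample %s shares no expressed genes with the "
                        "reference; TMM factor set to 1", exp.samples[j])
            continue
        ps = ns[both] / Ns
        pr = nr[both] / Nr
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        w = (Ns - ns[both]) / (Ns * ns[both]) + (Nr - nr[both]) / (Nr * nr[both])
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any():
            keep = np.ones_like(M, dtype=bool)
        factors[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        library_size=pd.Series(lib, index=exp.samples),
        tmm=pd.Series(factors, index=exp.samples),
    )


def compute_cpm(exp: CountsExperiment, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts per million on the TMM-scaled effective library size."""
    eff = factors.effective_size.loc[exp.samples]
    if (eff == 0).any():
        raise ValidationError("zero effective library size")
    return exp.counts / eff * 1e6


def filter_low_expression(cpm: pd.DataFrame, threshold: float = 1.0,
                          min_samples: int | None = None,
                          exp: CountsExperiment | None = None) -> list[str]:
    """Genes with CPM strictly above ``threshold`` in >= ``min_samples`` samples.

    Default quorum is the smallest design-cell size when the experiment is
    supplied, else 1.
    """
    if min_samples is None:
        if exp is not None:
            min_samples = int(
                exp.design.groupby(["group", "treatment"]).size().min()
            )
        else:
            min_samples = 1
    if min_samples > cpm.shape[1]:
        raise ValidationError("min_samples exceeds the sample count")
    keep = (cpm > threshold).sum(axis=1) >= min_samples
    return list(cpm.index[keep])


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    """A two-cell, within-group or interaction comparison.

    * ``kind='across'``: group_a vs group_b at one treatment
      (e.g. LR vs NR under Li-); tissue enters as a covariate.
    * ``kind='within'``: Li+ vs Li- inside one group, with subject fixed
      effects (samples are paired).
    * ``kind='interaction'``: group x treatment interaction between
      group_a and group_b across both treatments.
    """

    kind: str
    group_a: str | None = None
    group_b: str | None = None
    treatment: str | None = None
    group: str | None = None

    @property
    def label(self) -> str:
        if self.kind == "across":
            return f"{self.treatment}.{self.group_a} vs {self.treatment}.{self.group_b}"
        if self.kind == "within":
            return f"{self.group}: Li+ vs Li-"
        return f"interaction {self.group_a} x {self.group_b}"

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse ``'LR_vs_NR@Li-'``, ``'within:LR'`` or ``'interaction:LR:NR'``."""
        if text.startswith("within:"):
            return cls(kind="within", group=text.split(":", 1)[1])
        if text.startswith("interaction:"):
            _, a, b = text.split(":")
            return cls(kind="interaction", group_a=a, group_b=b)
        pair, treatment = text.split("@")
        a, b = pair.split("_vs_")
        return cls(kind="across", group_a=a, group_b=b, treatment=treatment)


@dataclass
class DEResult:
    """Per-gene DE statistics for one comparison plus filter flags."""

    comparison: str
    table: pd.DataFrame  # columns: mean_cpm_a, mean_cpm_b, log2fc, p, converged
    qvalue_scope: str = "serial"
    de_genes: list[str] = field(default_factory=list)


def _design_for_contrast(exp: CountsExperiment, contrast: Contrast):
    """Build (samples, X, test column index) for the contrast."""
    d = exp.design
    if contrast.kind == "across":
        sa = exp.samples_in_cell(contrast.group_a, contrast.treatment)
        sb = exp.samples_in_cell(contrast.group_b, contrast.treatment)
        if len(sa) < 2 or len(sb) < 2:
            raise ValidationError(
                f"contrast {contrast.label!r}: each design cell needs >= 2 samples"
            )
        samples = sb + sa  # baseline = group_b, so log2FC is a-over-b
        arm = np.array([0] * len(sb) + [1] * len(sa), dtype=float)
        cols = [np.ones(len(samples)), arm]
        names = ["intercept", "arm"]
        tissue = d.loc[samples, "tissue"]
        if tissue.nunique() > 1:
            cols.append((tissue == tissue.unique()[1]).to_numpy(float))
            names.append("tissue")
        X = np.column_stack(cols)
        return samples, X, 1
    if contrast.kind == "within":
        mask = d["group"] == contrast.group
        samples = list(d.index[mask])
        if len(samples) < 4:
            raise ValidationError(
                f"contrast {contrast.label!r}: too few samples"
            )
        sub = d.loc[samples]
        subjects = sorted(sub["subject"].unique())
        cols = [
            (sub["subject"] == s).to_numpy(float) for s in subjects
        ]  # subject fixed effects absorb the intercept
        arm = (sub["treatment"] == "Li+").to_numpy(float)
        X = np.column_stack(cols + [arm])
        return samples, X, X.shape[1] - 1
    if contrast.kind == "interaction":
        mask = d["group"].isin([contrast.group_a, contrast.group_b])
        samples = list(d.index[mask])
        sub = d.loc[samples]
        g = (sub["group"] == contrast.group_a).to_numpy(float)
        t = (sub["treatment"] == "Li+").to_numpy(float)
        cols = [np.ones(len(samples)), g, t, g * t]
        names = ["intercept", "group", "treatment", "interaction"]
        tissue = sub["tissue"]
        if tissue.nunique() > 1:
            cols.append((tissue == tissue.unique()[1]).to_numpy(float))
        X = np.column_stack(cols)
        return samples, X, 3
    raise ValidationError(f"unknown contrast kind {contrast.kind!r}")


def fit_de_model(exp: CountsExperiment, genes: list[str], contrast: Contrast,
                 factors: NormalizationFactors | None = None,
                 shrink_weight: float = 0.8) -> DEResult:
    """NB log-linear LRT for a contrast on the retained genes.

    Genewise dispersions are moment estimates from a Poisson fit, shrunk
    toward the common (median) dispersion with weight ``shrink_weight``;
    the p-value is a 1-df likelihood-ratio chi-square on the contrast
    coefficient and log2FC is that coefficient divided by log 2 (ridge
    regularization keeps it finite when an arm is all zero).
    """
    if factors is None:
        factors = tmm_factors(exp)
    samples, X, test_col = _design_for_contrast(exp, contrast)
    Y = exp.counts.loc[genes, samples].to_numpy(dtype=float)
    offset = np.log(factors.effective_size.loc[samples].to_numpy())

    # dispersion: Poisson fit -> moment estimate -> shrink to common
    _, mu0, _ = glm.nb_irls(Y, X, offset, alpha=0.0)
    disp = glm.moment_dispersion(Y, mu0, n_params=X.shape[1])
    common = float(np.median(disp))
    alpha = shrink_weight * common + (1.0 - shrink_weight) * disp

    X0 = np.delete(X, test_col, axis=1)
    beta1, mu1, conv1 = glm.nb_irls(Y, X, offset, alpha=alpha)
    _, mu0r, conv0 = glm.nb_irls(Y, X0, offset, alpha=alpha)
    ll1 = glm.nb_loglik(Y, mu1, alpha)
    ll0 = glm.nb_loglik(Y, mu0r, alpha)
    lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
    # F(1, residual df) reference rather than chi-square: with ~11-34
    # samples the asymptotic chi-square is anticonservative in the far
    # tail, which inflates the realized FDR; the F reference (in the
    # spirit of quasi-likelihood small-sample corrections) restores it.
    df_resid = max(len(samples) - X.shape[1], 1)
    p = stats.f.sf(lr, 1, df_resid)
    converged = conv1 & conv0
    p = np.where(converged, p, 1.0)
    n_bad = int((~converged).sum())
    if n_bad:
        log.warning("%s: %d genes failed to converge; p set to 1",
                    contrast.label, n_bad)
    log2fc = beta1[:, test_col] / LN2

    cpm = compute_cpm(exp, factors)
    if contrast.kind == "across":
        a_samp = exp.samples_in_cell(contrast.group_a, contrast.treatment)
        b_samp = exp.samples_in_cell(contrast.group_b, contrast.treatment)
    elif contrast.kind == "within":
        mask = exp.design["group"] == contrast.group
        a_samp = list(exp.design.index[mask & (exp.design["treatment"] == "Li+")])
        b_samp = list(exp.design.index[mask & (exp.design["treatment"] == "Li-")])
    else:
        a_samp = b_samp = samples
    table = pd.DataFrame(
        {
            "mean_cpm_a": cpm.loc[genes, a_samp].mean(axis=1),
            "mean_cpm_b": cpm.loc[genes, b_samp].mean(axis=1),
            "log2fc": log2fc,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "converged": converged,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(comparison=contrast.label, table=table)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN inputs propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return q
    from statsmodels.stats.multitest import multipletests

    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def serial_filter(de: DEResult, p_max: float = 0.05, lfc_min: float = 1.0,
                  q_max: float = 0.20, qvalue_scope: str = "serial") -> DEResult:
    """Apply the ordered DE filters: p, |log2FC|, then B-H q.

    ``qvalue_scope='serial'`` computes q over genes surviving the p and
    log2FC gates (the default); ``'genome_wide'`` adjusts over all tested
    genes. Flags ``pass_p``, ``pass_lfc``, ``pass_q`` are monotone: a gene
    passing stage j passed every earlier stage. DE genes are ordered by
    q, then p, then symbol.
    """
    t = de.table.copy()
    t["pass_p"] = t["p"] < p_max
    t["pass_lfc"] = t["pass_p"] & (t["log2fc"].abs() >= lfc_min)
    t["q"] = np.nan
    if qvalue_scope == "serial":
        surv = t.index[t["pass_lfc"]]
        if len(surv):
            t.loc[surv, "q"] = bh_adjust(t.loc[surv, "p"])
    elif qvalue_scope == "genome_wide":
        t["q"] = bh_adjust(t["p"])
    else:
        raise ValidationError(f"unknown qvalue_scope {qvalue_scope!r}")
    t["pass_q"] = t["pass_lfc"] & (t["q"] <= q_max)
    t["direction"] = np.where(t["log2fc"] >= 0, "up", "down")
    de_tab = t[t["pass_q"]].copy()
    de_tab = de_tab.assign(_g=de_tab.index).sort_values(
        ["q", "p", "_g"], kind="mergesort"
    )
    out = DEResult(comparison=de.comparison, table=t, qvalue_scope=qvalue_scope,
                   de_genes=list(de_tab.index))
    log.info("%s: %d DE genes (q scope: %s)", de.comparison, len(out.de_genes),
             qvalue_scope)
    return out


def compare_de_lists(lists: dict[str, list[str]]) -> pd.DataFrame:
    """Venn-region counts and shared identities for >= 2 named gene lists."""
    if len(lists) < 2:
        raise ValidationError("need at least two lists")
    names = list(lists)
    sets = {k: set(v) for k, v in lists.items()}
    universe = set().union(*sets.values())
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for k in combo:
                inside &= sets[k]
            for k in names:
                if k not in combo:
                    inside -= sets[k]
            union = set().union(*(sets[k] for k in combo))
            pct = 100.0 * len(inside) / len(union) if union else 0.0
            rows.append(
                {
                    "region": "&".join(combo),
                    "exclusive_count": len(inside),
                    "genes": ";".join(sorted(inside)),
                    "pct_of_union": round(pct, 2),
                }
            )
    rows.append({"region": "union", "exclusive_count": len(universe),
                 "genes": ";".join(sorted(universe)), "pct_of_union": 100.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR validation utilities
# ---------------------------------------------------------------------------

def ddct_fold_change(ct_target_cond, ct_reference_cond,
                     ct_target_base, ct_reference_base) -> tuple[float, float]:
    """Relative fold change by the 2^-ddCt method with propagated SEM.

    Per replicate dCt = Ct_target - Ct_reference; ddCt = mean dCt(condition)
    - mean dCt(baseline); FC = 2^-ddCt. The SEM of ddCt combines the
    replicate variances of both arms and is propagated to the FC scale as
    FC * ln2 * SEM(ddCt).
    """
    for arr in (ct_reference_cond, ct_reference_base):
        if arr is None or len(np.atleast_1d(arr)) == 0:
            raise ValidationError("reference-gene Ct values are required")
    dct_c = np.asarray(ct_target_cond, float) - np.asarray(ct_reference_cond, float)
    dct_b = np.asarray(ct_target_base, float) - np.asarray(ct_reference_base, float)
    ddct = dct_c.mean() - dct_b.mean()
    var = 0.0
    if dct_c.size > 1:
        var += dct_c.var(ddof=1) / dct_c.size
    if dct_b.size > 1:
        var += dct_b.var(ddof=1) / dct_b.size
    sem_ddct = np.sqrt(var)
    fc = 2.0 ** (-ddct)
    return float(fc), float(fc * LN2 * sem_ddct)


def log2fc_concordance(x, y) -> tuple[float, float]:
    """Squared Pearson correlation of paired log2FC vectors and its p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: R^2 undefined")
    r, p = stats.pearsonr(x, y)
    return float(r**2), float(p)
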