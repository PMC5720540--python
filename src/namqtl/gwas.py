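"""Multi-locus joint-linkage association scan.

The scan regresses per-line BLUEs on wild-allele dosage columns.  A set
of cofactor SNPs is first chosen by stepwise forward-backward selection
minimizing the Schwarz Bayesian Criterion; each SNP is then tested with
a 1-df nested-model F test (full model = intercept + cofactors + SNP,
reduced model = the same without the SNP).  P-values are adjusted by the
Bonferroni-Holm step-down procedure and a SNP is significant below 0.05
after adjustment.  The allele-substitution effect is twice the fitted
dosage coefficient (replacing both recurrent alleles with wild alleles).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_snps",
    "impute_dosages",
    "holm_adjust",
    "sbc",
    "select_cofactors",
    "scan",
    "snp_r2",
    "multi_marker_r2_adj",
]

log = logging.getLogger(__name__)

VALID_DOSAGES = (0, 1, 2)

#: relative RSS floor guarding log(0) in the SBC for (near-)perfect fits
_RSS_FLOOR = 1e-12


class GwasError(ValueError):
    pass


def _check_alignment(genotypes: pd.DataFrame, blues: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    common = genotypes.index.intersection(blues.index)
    if len(common) == 0:
        raise GwasError("no lines shared between genotypes and BLUEs")
    return genotypes.loc[common], blues.loc[common].astype(float)


def filter_snps(
    genotypes: pd.DataFrame,
    families: pd.Series | None = None,
    max_missing: float = 0.10,
    max_het: float = 0.125,
) -> pd.Index:
    """SNP quality control.

    Retains SNPs that (a) are polymorphic — within at least one family
    when a family assignment is given, otherwise overall; (b) have a
    missing fraction strictly below ``max_missing``; and (c) have a
    heterozygous-call fraction strictly below ``max_het``.  Fractions use
    all lines in the denominator.
    """
    if genotypes.empty:
        raise GwasError("empty genotype matrix")
    n = len(genotypes)
    vals = genotypes.to_numpy(dtype=float)
    missing_frac = np.isnan(vals).mean(axis=0)
    het_frac = np.nansum(vals == 1, axis=0) / n

    if families is None:
        groups = [np.arange(n)]
    else:
        fam = families.reindex(genotypes.index)
        groups = [np.flatnonzero((fam == f).to_numpy()) for f in fam.dropna().unique()]
    poly = np.zeros(vals.shape[1], dtype=bool)
    for idx in groups:
        sub = vals[idx]
        with np.errstate(invalid="ignore"):
            mn = np.nanmin(sub, axis=0)
            mx = np.nanmax(sub, axis=0)
        poly |= np.nan_to_num(mx - mn) > 0
    keep = poly & (missing_frac < max_missing) & (het_frac < max_het)
    return genotypes.columns[keep]


def impute_dosages(genotypes: pd.DataFrame, families: pd.Series | None = None) -> pd.DataFrame:
    """Mean-impute missing dosages per SNP, within family when given.

    Family-wise imputation preserves the nested population structure; a
    value still missing after that (SNP untyped in a whole family) falls
    back to the overall SNP mean, then to 0.
    """
    out = genotypes.astype(float)
    if families is not None:
        fam = families.reindex(out.index).to_numpy()
        fam_means = out.groupby(fam).mean()
        fill = fam_means.loc[fam].set_axis(out.index)
        out = out.where(out.notna(), fill)
    out = out.fillna(out.mean())
    return out.fillna(0.0)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise GwasError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise GwasError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def sbc(rss: float, n: int, k: int, tss: float | None = None) -> float:
    """Schwarz Bayesian Criterion: n*ln(RSS/n) + k*ln(n).

    ``k`` counts the intercept and every covariate.  RSS is floored at a
    tiny fraction of the total sum of squares so that perfect fits get a
    finite, stable score.
    """
    floor = _RSS_FLOOR * (tss if tss and tss > 0 else 1.0)
    rss = max(float(rss), floor)
    return n * np.log(rss / n) + k * np.log(n)


def select_cofactors(
    genotypes: pd.DataFrame,
    blues: pd.Series,
    candidates=None,
    max_steps: int = 200,
) -> list[str]:
    """Stepwise forward-backward SNP selection minimizing the SBC.

    Starts from the empty model (intercept only).  Each iteration scores
    every single addition and every single removal and takes the move
    with the largest SBC decrease; the search stops when no move strictly
    lowers the criterion.  Ties are broken by the entering SNP's partial
    p-value, then lexicographically by snp_id.
    """
    G, y = _check_alignment(genotypes, blues)
    n = len(y)
    if n < 3:
        raise GwasError("need at least three lines for cofactor selection")
    cand = list(G.columns if candidates is None else candidates)
    yv = y.to_numpy()
    tss = float(np.sum((yv - yv.mean()) ** 2))
    X_all = G[cand].to_numpy(dtype=float)

    selected: list[str] = []
    cur_X = np.ones((n, 1))
    cur_rss = tss
    cur_sbc = sbc(cur_rss, n, 1, tss)

    for _ in range(max_steps):
        best = None  # (sbc, p_entry, snp, kind, rss)

        # forward: RSS drop from adding one residualized column
        out = [s for s in cand if s not in selected]
        if out:
            Q, _ = np.linalg.qr(cur_X)
            y_res = yv - Q @ (Q.T @ yv)
            C = X_all[:, [cand.index(s) for s in out]]
            C_res = C - Q @ (Q.T @ C)
            norms = np.einsum("ij,ij->j", C_res, C_res)
            dots = C_res.T @ y_res
            with np.errstate(divide="ignore", invalid="ignore"):
                drop = np.where(norms > 1e-10 * n, dots**2 / norms, 0.0)
            k_new = cur_X.shape[1] + 1
            df_err = n - k_new
            for j, s in enumerate(out):
                if norms[j] <= 1e-10 * n or df_err <= 0:
                    continue
                rss_new = max(cur_rss - drop[j], 0.0)
                crit = sbc(rss_new, n, k_new, tss)
                if rss_new > 0 and df_err > 0:
                    f = drop[j] / (rss_new / df_err) if rss_new > 0 else np.inf
                    p_entry = float(stats.f.sf(f, 1, df_err))
                else:
                    p_entry = 0.0
                move = (crit, p_entry, s, "add", rss_new)
                if best is None or move[:3] < best[:3]:
                    best = move

        # backward: refit without each selected SNP
        for s in selected:
            rest = [t for t in selected if t != s]
            X_new = np.hstack([np.ones((n, 1)), G[rest].to_numpy(dtype=float)])
            rss_new = _rss(X_new, yv)
            crit = sbc(rss_new, n, X_new.shape[1], tss)
            move = (crit, 0.0, s, "drop", rss_new)
            if best is None or move[:3] < best[:3]:
                best = move

        if best is None or best[0] >= cur_sbc - 1e-10:
            break
        crit, _, s, kind, rss_new = best
        if kind == "add":
            selected.append(s)
        else:
            selected.remove(s)
        cur_X = np.hstack([np.ones((n, 1)), G[selected].to_numpy(dtype=float)])
        cur_rss = _rss(cur_X, yv)  # refit exactly to avoid drift
        cur_sbc = sbc(cur_rss, n, cur_X.shape[1], tss)
    return selected


def scan(
    genotypes: pd.DataFrame,
    blues: pd.Series,
    cofactors: list[str] | None = None,
    gmap=None,
    alpha_level: float = 0.05,
    cofactor_window_cm: float | None = None,
) -> pd.DataFrame:
    """Per-SNP nested-model F tests against the cofactor background.

    For each SNP the reduced model (intercept + cofactors, the tested SNP
    removed from the cofactor set if present — optionally along with any
    cofactor within ``cofactor_window_cm`` of it) is compared with the
    full model that adds the SNP's dosage.  Returns one row per SNP with
    the dosage coefficient ``alpha``, the allele-substitution ``effect``
    (2 * alpha), raw and Holm-adjusted p-values, a significance flag at
    ``p_holm < alpha_level``, the single-SNP R², and a ``degenerate``
    flag for SNPs collinear with their reduced model (p = 1, alpha = 0).
    """
    G, y = _check_alignment(genotypes, blues)
    cofactors = list(cofactors or [])
    unknown = [c for c in cofactors if c not in G.columns]
    if unknown:
        raise GwasError(f"cofactors absent from genotypes: {unknown}")
    n = len(y)
    yv = y.to_numpy()
    snps = list(G.columns)
    X = G.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise GwasError("genotypes contain missing dosages; impute first")

    pos = chrom = None
    if gmap is not None:
        pos = gmap.positions(snps)
        chrom = gmap.chromosome_of(snps)

    def reduced_set(snp: str) -> tuple[str, ...]:
        keep = [c for c in cofactors if c != snp]
        if cofactor_window_cm is not None and gmap is not None:
            keep = [
                c
                for c in keep
                if chrom[c] != chrom[snp] or abs(pos[c] - pos[snp]) > cofactor_window_cm
            ]
        return tuple(keep)

    # group SNPs sharing a reduced model so the QR is computed once
    groups: dict[tuple[str, ...], list[int]] = {}
    for j, s in enumerate(snps):
        groups.setdefault(reduced_set(s), []).append(j)

    alpha = np.zeros(len(snps))
    pval = np.ones(len(snps))
    degen = np.zeros(len(snps), dtype=bool)
    for red, idx in groups.items():
        Xr = np.hstack([np.ones((n, 1)), G[list(red)].to_numpy(dtype=float)])
        Q, _ = np.linalg.qr(Xr)
        k_red = Xr.shape[1]
        y_res = yv - Q @ (Q.T @ yv)
        rss_red = float(y_res @ y_res)
        C = X[:, idx]
        C_res = C - Q @ (Q.T @ C)
        norms = np.einsum("ij,ij->j", C_res, C_res)
        dots = C_res.T @ y_res
        df_err = n - k_red - 1
        for jj, j in enumerate(idx):
            if norms[jj] <= 1e-10 * n or df_err <= 0:
                degen[j] = True
                continue
            a = dots[jj] / norms[jj]
            rss_full = max(rss_red - dots[jj] ** 2 / norms[jj], 0.0)
            alpha[j] = a
            if rss_full <= _RSS_FLOOR * max(rss_red, 1.0):
                pval[j] = 0.0
            else:
                f = (rss_red - rss_full) / (rss_full / df_err)
                pval[j] = float(stats.f.sf(f, 1, df_err))

    p_holm = holm_adjust(pval)
    res = pd.DataFrame(
        {
            "snp_id": snps,
            "alpha": alpha,
            "effect": 2.0 * alpha,
            "p_value": pval,
            "p_holm": p_holm,
            "significant": (p_holm < alpha_level) & ~degen,
            "r2_single": [snp_r2(G[s], y, strict=False) for s in snps],
            "degenerate": degen,
        }
    )
    if gmap is not None:
        res.insert(1, "chromosome", chrom.to_numpy())
        res.insert(2, "position_cm", pos.to_numpy())
    return res


def snp_r2(dosage_column: pd.Series, blues: pd.Series, strict: bool = True) -> float:
    """Variance explained by one SNP alone (single-regressor R²)."""
    d = dosage_column.reindex(blues.index).to_numpy(dtype=float)
    y = blues.to_numpy(dtype=float)
    if np.ptp(d) == 0:
        if strict:
            raise GwasError("constant dosage column: R² undefined")
        return float("nan")
    X = np.column_stack([np.ones_like(d), d])
    rss = _rss(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return float("nan")
    return 1.0 - rss / tss


def multi_marker_r2_adj(
    genotypes: pd.DataFrame, blues: pd.Series, snps: list[str]
) -> float:
    """Adjusted R² of the joint fit of all given SNP dosages.

    R²_adj = 1 - (1 - R²) (n - 1) / (n - k - 1), with k the number of
    fitted SNP columns.
    """
    if len(snps) == 0:
        raise GwasError("need at least one significant SNP")
    G, y = _check_alignment(genotypes[list(snps)], blues)
    n, k = len(y), len(snps)
    if k >= n - 1:
        raise GwasError(f"too many SNPs ({k}) for {n} lines")
    yv = y.to_numpy()
    X = np.hstack([np.ones((n, 1)), G.to_numpy(dtype=float)])
    rss = _rss(X, yv)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        raise GwasError("constant BLUEs: R² undefined")
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
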