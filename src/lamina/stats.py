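"""Within-subject statistics: repeated-measures ANOVA with sphericity
handling, paired t-tests, Cousineau-Morey SEM, and Benjamini-Hochberg FDR.

The ANOVA handles up to three fully crossed within-subject factors on a
complete balanced table (one observation per subject x cell).  Each
effect is tested through its set of orthonormalised contrasts D (subjects
x q): F = (n * sum d_bar^2 / q) / (SS_resid / (q (n-1))).  The
Greenhouse-Geisser epsilon and Mauchly's W come from the covariance of D;
following common practice the GG-corrected p is reported when
epsilon < 0.75 (two-level effects have epsilon = 1 by definition and skip
sphericity).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GG_EPSILON_RULE = 0.75


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows sum to zero)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1)
        h[i] /= np.linalg.norm(h[i])
    return h


@dataclass
class RMAnovaResult:
    """Per-effect F table with sphericity diagnostics.

    ``table`` columns: effect, df1, df2, F, p, eps_gg, df1_gg, df2_gg,
    p_gg, mauchly_w, mauchly_p, p_reported (GG-corrected when
    eps_gg < 0.75 and the effect has > 1 df, uncorrected otherwise).
    """

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}; "
                           f"have {list(self.table['effect'])}")
        return rows.iloc[0]


def rm_anova(data: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject") -> RMAnovaResult:
    """Repeated-measures ANOVA on a complete balanced long table.

    ``within`` lists 1-3 fully crossed within-subject factor columns;
    every subject must contribute exactly one value per cell.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("rm_anova supports 1 to 3 within factors")
    levels = {f: list(dict.fromkeys(data[f])) for f in within}
    subjects = list(dict.fromkeys(data[subject]))
    n = len(subjects)
    if n < 3:
        raise ValueError("need >= 3 subjects")

    shape = [len(levels[f]) for f in within]
    cells = np.full([n] + shape, np.nan)
    idx = {f: {lv: i for i, lv in enumerate(levels[f])} for f in within}
    sidx = {s: i for i, s in enumerate(subjects)}
    for _, row in data.iterrows():
        pos = (sidx[row[subject]],) + tuple(idx[f][row[f]] for f in within)
        if not np.isnan(cells[pos]):
            raise ValueError(f"duplicate observation in cell {pos[1:]}")
        cells[pos] = row[dv]
    if np.isnan(cells).any():
        missing = list(zip(*np.nonzero(np.isnan(cells))))
        raise ValueError(f"missing cells (subject, *levels indices): "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    y = cells.reshape(n, -1)

    rows = []
    for r in range(1, len(within) + 1):
        for effect in combinations(range(len(within)), r):
            mats = []
            for f_i, f in enumerate(within):
                k = len(levels[f])
                mats.append(_orthonormal_contrasts(k) if f_i in effect
                            else np.ones((1, k)) / np.sqrt(k))
            m = mats[0]
            for extra in mats[1:]:
                m = np.kron(m, extra)
            d = y @ m.T                       # n x q contrast scores
            q = d.shape[1]
            dbar = d.mean(axis=0)
            ss_eff = n * (dbar**2).sum()
            ss_err = ((d - dbar)**2).sum()
            df1, df2 = q, q * (n - 1)
            f_val = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(f_val, df1, df2))

            if q == 1:
                eps = 1.0
                w = mauchly_p = np.nan
            else:
                s = np.cov(d, rowvar=False, ddof=1)
                tr = np.trace(s)
                eps = float(tr**2 / (q * np.trace(s @ s)))
                det = np.linalg.det(s)
                w = float(det / (tr / q) ** q) if det > 0 else 0.0
                # chi-square approximation with the second-order term
                # (as in ezANOVA / SAS)
                dfw = q * (q + 1) / 2 - 1
                fcorr = 1 - (2 * q**2 + q + 2) / (6 * q * (n - 1))
                k = q + 1
                w2 = ((q + 2) * (q - 1) * (q - 2)
                      * (2 * q**3 + 6 * q**2 + 3 * k + 2)
                      / (288 * ((n - 1) * q * fcorr) ** 2))
                if w > 0:
                    chi2 = -(n - 1) * fcorr * np.log(w)
                    p1 = sps.chi2.sf(chi2, dfw)
                    p2 = sps.chi2.sf(chi2, dfw + 4)
                    mauchly_p = float(p1 + w2 * (p2 - p1))
                else:
                    mauchly_p = 0.0
            df1_gg, df2_gg = df1 * eps, df2 * eps
            p_gg = float(sps.f.sf(f_val, df1_gg, df2_gg))
            use_gg = q > 1 and eps < GG_EPSILON_RULE
            rows.append({
                "effect": " x ".join(within[i] for i in effect),
                "df1": df1, "df2": df2, "F": float(f_val), "p": p,
                "eps_gg": eps, "df1_gg": df1_gg, "df2_gg": df2_gg,
                "p_gg": p_gg, "mauchly_w": w, "mauchly_p": mauchly_p,
                "gg_applied": use_gg,
                "p_reported": p_gg if use_gg else p})
    return RMAnovaResult(table=pd.DataFrame(rows))


def paired_t(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).  Zero-variance
    differences give (nan, df, nan)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length vectors, n >= 2")
    diff = a - b
    df = len(a) - 1
    if np.all(diff == 0):
        return 0.0, df, 1.0
    if np.std(diff, ddof=1) == 0:
        return float("nan"), df, float("nan")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), df, float(res.pvalue)


def cousineau_morey_sem(data: pd.DataFrame) -> pd.Series:
    """Within-subject SEM per condition (Cousineau normalisation with the
    Morey bias correction).

    ``data`` is a wide subject x condition table; each value is first
    re-centred by the subject mean plus the grand mean, the per-condition
    SD over subjects is divided by sqrt(n), and the result scaled by
    sqrt(C/(C-1)).
    """
    if data.isna().any().any():
        raise ValueError("incomplete subject x condition table")
    n, c = data.shape
    if n < 2 or c < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    vals = data.to_numpy(dtype=float)
    norm = vals - vals.mean(axis=1, keepdims=True) + vals.mean()
    sem = norm.std(axis=0, ddof=1) / np.sqrt(n) * np.sqrt(c / (c - 1))
    return pd.Series(sem, index=data.columns, name="sem")


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
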