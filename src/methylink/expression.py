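"""Differential-expression statistics for transcript arrays and proteome intensities.

Transcript matrices are assumed normalized upstream (array-vendor pipeline);
values are tested per gene with a Welch unequal-variance t-test on the log2
scale, and significance follows the raw p < alpha rule used for array data.
Proteome intensity tables are log2-transformed, missing values are imputed
with the lowest observed intensity (missing-not-at-random dropout sits at
the low end of the dynamic range, so the detection floor is the natural
imputation value), and significance uses Benjamini-Hochberg q < q_alpha.

Sample columns are named ``condition_replicate`` (e.g. ``T26_1``); the
condition label is everything before the final underscore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    log2fc: float
    t_stat: float
    df: float
    p_value: float
    q_value: float
    significant: bool
    tested: bool = True
    note: str = ""


def condition_of(column: str) -> str:
    """Condition label of a ``condition_replicate`` sample column."""
    return column.rsplit("_", 1)[0]


def condition_columns(matrix: pd.DataFrame, condition: str) -> list[str]:
    cols = [c for c in matrix.columns if condition_of(c) == condition]
    if not cols:
        raise KeyError(f"no sample columns for condition {condition!r}")
    return cols


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch unequal-variance t statistic, Satterthwaite df, two-sided p.

    Degenerate conventions: both groups zero-variance with equal means ->
    (0, df, 1); zero variance with unequal means -> (inf-signed, df, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _de_table(
    matrix: pd.DataFrame,
    treatment: str,
    control: str,
    log_transform: bool,
    student: bool = False,
) -> list[dict]:
    t_cols = condition_columns(matrix, treatment)
    c_cols = condition_columns(matrix, control)
    rows = []
    for fid, row in matrix.iterrows():
        a = row[t_cols].astype(float).dropna().to_numpy()
        b = row[c_cols].astype(float).dropna().to_numpy()
        if log_transform:
            a, b = np.log2(a), np.log2(b)
        if len(a) < 2 or len(b) < 2:
            rows.append(
                dict(feature_id=str(fid), log2fc=np.nan, t=np.nan, df=np.nan,
                     p=np.nan, tested=False, note="insufficient_replicates")
            )
            continue
        if student:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            df = float(len(a) + len(b) - 2)
            t, p = float(t), float(p)
            if math.isnan(p):  # zero-variance degenerate
                t, df, p = welch_t(a, b)
        else:
            t, df, p = welch_t(a, b)
        note = "degenerate_zero_variance" if p in (0.0,) and math.isinf(t) else ""
        rows.append(
            dict(feature_id=str(fid), log2fc=float(a.mean() - b.mean()),
                 t=t, df=df, p=p, tested=True, note=note)
        )
    return rows


def _attach_q(rows: list[dict], sig_on: str, alpha: float) -> list[DEResult]:
    tested = [r for r in rows if r["tested"]]
    qs = bh_fdr([r["p"] for r in tested]) if tested else np.array([])
    for r, q in zip(tested, qs):
        r["q"] = float(q)
    out = []
    for r in rows:
        q = r.get("q", np.nan)
        crit = r["p"] if sig_on == "p" else q
        out.append(
            DEResult(
                feature_id=r["feature_id"],
                log2fc=r["log2fc"],
                t_stat=r["t"],
                df=r["df"],
                p_value=r["p"],
                q_value=q,
                significant=bool(r["tested"] and not math.isnan(crit) and crit < alpha),
                tested=r["tested"],
                note=r["note"],
            )
        )
    return out


def transcript_de(
    matrix: pd.DataFrame, treatment: str, control: str, alpha: float = 0.05
) -> list[DEResult]:
    """Per-gene Welch test on log2 intensities; significant iff raw p < alpha.

    BH q-values are computed and reported alongside but do not gate the
    transcript significance call.
    """
    rows = _de_table(matrix, treatment, control, log_transform=True)
    return _attach_q(rows, sig_on="p", alpha=alpha)


def proteome_preprocess(matrix: pd.DataFrame, per_sample_min: bool = False) -> pd.DataFrame:
    """log2-transform intensities and impute missing cells with the lowest intensity.

    Default imputes with the single matrix-wide minimum observed log2
    intensity; ``per_sample_min`` switches to column-wise minima.
    Rows missing in every sample are imputed to the global minimum too
    (flagged by the caller via their all-equal constant value).
    """
    values = matrix.astype(float)
    if (values <= 0).any().any():
        raise ValueError("intensities must be positive where present")
    logged = np.log2(values)
    if per_sample_min:
        fill = logged.min(axis=0)
        return logged.fillna(fill)
    return logged.fillna(logged.min().min())


def proteome_de(
    matrix: pd.DataFrame,
    treatment: str,
    control: str,
    q_alpha: float = 0.05,
    student: bool = False,
) -> list[DEResult]:
    """Per-protein two-sample test on a preprocessed (log2, imputed) matrix.

    Significant iff BH q < q_alpha. Default test is Welch; ``student=True``
    uses the equal-variance Student statistic.
    """
    rows = _de_table(matrix, treatment, control, log_transform=False, student=student)
    return _attach_q(rows, sig_on="q", alpha=q_alpha)


# ---------------------------------------------------------------------------
# I/O


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV with a feature_id column; returns indexed DataFrame."""
    df = pd.read_csv(str(path), sep="\t")
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: expected a feature_id column")
    df = df.set_index("feature_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate feature_ids")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.round(6).rename_axis("feature_id").to_csv(str(path), sep="\t")


def de_results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "log2fc": r.log2fc,
                "t_stat": r.t_stat,
                "df": r.df,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
                "tested": r.tested,
                "note": r.note,
            }
            for r in results
        ]
    )


def write_de_tsv(results: Sequence[DEResult], path: str | Path) -> None:
    de_results_frame(results).to_csv(str(path), sep="\t", index=False)


def pca_export(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample-level PCA coordinates via SVD (descriptive QC convenience only)."""
    x = matrix.T.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    return pd.DataFrame(
        coords, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
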