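"""Genome-wide driver: fit every gene, assemble the partition table,
summarize, and relate gene-level fractions to external gene annotations.

Each gene is an independent fit of the same design, so genes are processed
as pure per-gene tasks; results are identical for any worker count and any
gene order.  Non-converged and degenerate genes are flagged in the run
report, never dropped silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import DesignBundle, ModelSpec, align_expression, build_design, parse_formula
from .lmm import fit_lmm_ml
from .partition import PartitionRow, PartitionTable, partition_fractions, partition_varying

__all__ = ["RunConfig", "run_genomewide", "summarize", "binned_curve", "BinnedCurve"]


@dataclass
class RunConfig:
    """Paths and options for one genome-wide run (CLI/config surface)."""

    expression: str
    metadata: str
    model: str
    weights: str | None = None
    method: str = "ML"
    weight_convention: str = "precision"
    n_jobs: int = 1
    output_dir: str = "varipart_out"
    seed: int = 0
    sample_col: str | None = None
    column_types: dict[str, str] = field(default_factory=dict)


def _fit_one(y, designs, w, method, convention, varying):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_lmm_ml(
                y, designs, weights=w, method=method, weight_convention=convention
            )
        if varying:
            return partition_varying(fit, designs), None
        return partition_fractions(fit, designs), None
    except Exception as exc:  # pragma: no cover - per-gene failures are rare
        return None, str(exc)


def run_genomewide(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    spec: ModelSpec | str,
    weights: pd.DataFrame | None = None,
    method: str = "ML",
    weight_convention: str = "precision",
    n_jobs: int = 1,
) -> tuple[PartitionTable, dict]:
    """Fit the mixed model for every gene and return the partition table.

    ``expression`` is genes × samples; ``metadata`` is indexed by sample id
    (alignment is by id, never by position).  Returns the table plus a run
    report with convergence/flag accounting.
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    expression = align_expression(expression, metadata)
    if weights is not None:
        weights = align_expression(weights, metadata)
        if list(weights.index) != list(expression.index):
            raise ValueError("weights and expression gene ids disagree")
    designs = build_design(metadata, spec)
    varying = bool(designs.varying_parent)

    Y = expression.to_numpy(dtype=float)
    genes = list(expression.index)
    constant = np.nanstd(Y, axis=1) == 0

    tasks = []
    for i, g in enumerate(genes):
        if constant[i]:
            continue
        w = weights.iloc[i].to_numpy() if weights is not None else None
        tasks.append((g, Y[i], w))
    results = Parallel(n_jobs=n_jobs)(
        delayed(_fit_one)(y, designs, w, method, weight_convention, varying)
        for _, y, w in tasks
    )

    term_template = None
    rows: dict[str, PartitionRow] = {}
    failed: dict[str, str] = {}
    for (g, _, _), (row, err) in zip(tasks, results):
        if row is None:
            failed[g] = err
        else:
            rows[g] = row
            term_template = row.terms
    if term_template is None:
        raise ValueError("no gene could be fit; check the model and inputs")
    for i, g in enumerate(genes):
        if constant[i]:
            fr = {t: 0.0 for t in term_template}
            fr["residual"] = 1.0
            rows[g] = PartitionRow(fr, sums_to_one=True, flags=["constant"])
        elif g in failed:
            fr = {t: float("nan") for t in term_template}
            rows[g] = PartitionRow(fr, sums_to_one=False, flags=["failed"])
    rows = {g: rows[g] for g in genes}  # restore input order
    table = PartitionTable.from_rows(rows, model=spec.formula())

    n_flagged = sum(1 for r in rows.values() if r.flags)
    report = {
        "n_genes": len(genes),
        "n_ok": len(genes) - n_flagged,
        "n_flagged": n_flagged,
        "flagged": {g: r.flags for g, r in rows.items() if r.flags},
        "failed": failed,
        "model": spec.formula(),
        "method": method,
    }
    return table, report


def summarize(table: PartitionTable, thresholds=(0.25, 0.5)) -> pd.DataFrame:
    """Genome-wide per-term summary, ranked by median fraction.

    Returns one row per term (residual last) with the median, quartiles and
    the number of genes whose fraction exceeds each threshold.  Degenerate
    and non-converged genes are excluded from the statistics.
    """
    df = table.clean()
    if df.empty:
        raise ValueError("no usable rows to summarize")
    out = pd.DataFrame(
        {
            "median": df.median(),
            "q25": df.quantile(0.25),
            "q75": df.quantile(0.75),
        }
    )
    for thr in thresholds:
        out[f"n_gt_{thr}"] = (df > thr).sum()
    resid = [t for t in out.index if t == "residual"]
    rest = out.drop(index=resid).sort_values("median", ascending=False)
    out = pd.concat([rest, out.loc[resid]])
    out.index.name = "term"
    return out


@dataclass
class BinnedCurve:
    """Sliding-window and logistic-smoothed outcome probability vs fraction."""

    window_x: np.ndarray
    window_p: np.ndarray
    smooth_x: np.ndarray
    smooth_p: np.ndarray
    baseline: float
    slope: float
    pvalue: float
    window: int
    overlap: int


def binned_curve(
    x, flag, window: int = 200, overlap: int = 100, n_smooth: int = 200
) -> BinnedCurve:
    """Probability of a binary gene annotation as a function of a fraction.

    Genes are sorted by ``x``; a sliding window of ``window`` genes
    (overlapping by ``overlap``) gives the empirical outcome probability at
    the window's mean ``x``.  A logistic regression of ``flag`` on ``x``
    gives the smoothed curve, with the genome-wide mean as reference.
    """
    x = np.asarray(x, dtype=float)
    flag = np.asarray(flag, dtype=float)
    if x.shape != flag.shape:
        raise ValueError("x and flag must align gene-by-gene")
    if overlap >= window:
        raise ValueError("window must exceed overlap")
    n = x.size
    if n < window:
        warnings.warn(
            f"only {n} genes for window size {window}; using a single window",
            RuntimeWarning,
            stacklevel=2,
        )
        window = n
        overlap = 0
    order = np.argsort(x, kind="stable")
    xs, fs = x[order], flag[order]
    step = window - overlap
    starts = list(range(0, max(n - window, 0) + 1, step))
    wx = np.array([xs[s : s + window].mean() for s in starts])
    wp = np.array([fs[s : s + window].mean() for s in starts])

    grid = np.linspace(x.min(), x.max(), n_smooth)
    if np.all(flag == flag[0]):
        smooth = np.full(n_smooth, flag[0])
        slope, pval = 0.0, 1.0
    else:
        import statsmodels.api as sm

        X = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(flag, X, family=sm.families.Binomial()).fit()
        slope = float(res.params[1])
        pval = float(res.pvalues[1])
        smooth = res.predict(sm.add_constant(grid))
    return BinnedCurve(
        window_x=wx,
        window_p=wp,
        smooth_x=grid,
        smooth_p=np.asarray(smooth),
        baseline=float(flag.mean()),
        slope=slope,
        pvalue=pval,
        window=window,
        overlap=overlap,
    )
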