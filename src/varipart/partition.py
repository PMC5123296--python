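"""Variance fractions from fitted models.

Each fitted gene yields one variance component per random term, a residual
variance, and a post-hoc variance var(X_j b_j) for every fixed term.  The
total is their sum and the fraction of variance explained (FVE) by a term
is its component divided by that total; for a standard model the fractions
are non-negative and sum to one.  The fraction of a random term equals the
intra-class correlation between two samples sharing that term's level.

Varying-coefficient fits are partitioned per stratifier level: each
subset-specific component is divided by a subset-specific total (that
subset's component, plus shared random components and the residual, plus
the fixed-term contributions evaluated within the subset), so the reported
fractions no longer sum to one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignBundle
from .lmm import FitResult

__all__ = [
    "PartitionRow",
    "PartitionTable",
    "fixed_effect_variance",
    "partition_fractions",
    "partition_varying",
    "icc",
]

SUM_TOL = 1e-6


def fixed_effect_variance(
    X_j: np.ndarray, beta_j: np.ndarray, subset: np.ndarray | None = None, ddof: int = 1
) -> float:
    """Post-hoc variance of a fixed term: var(X_j @ beta_j) across samples.

    Sample variance with denominator n-1 by default (``ddof`` configurable).
    A constant contribution (intercept-like column, or all-zero
    coefficients) has variance 0.
    """
    X_j = np.asarray(X_j, dtype=float)
    beta_j = np.asarray(beta_j, dtype=float).ravel()
    if X_j.ndim == 1:
        X_j = X_j[:, None]
    if X_j.shape[1] != beta_j.shape[0]:
        raise ValueError(
            f"design has {X_j.shape[1]} columns but {beta_j.shape[0]} coefficients"
        )
    contrib = X_j @ beta_j
    if subset is not None:
        contrib = contrib[subset]
    if contrib.size <= ddof:
        return 0.0
    return float(np.var(contrib, ddof=ddof))


@dataclass
class PartitionRow:
    """Variance fractions for one gene, keyed by term name plus 'residual'."""

    fractions: dict[str, float]
    sums_to_one: bool
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> float:
        return self.fractions[term]

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.fractions)


def _components(fit: FitResult, designs: DesignBundle) -> dict[str, float]:
    comps: dict[str, float] = {}
    for t in fit.beta:
        comps[t] = fixed_effect_variance(designs.fixed_encoding(t), fit.beta[t])
    for t, v in fit.var_random.items():
        comps[t] = float(v)
    return comps


def partition_fractions(fit: FitResult, designs: DesignBundle) -> PartitionRow:
    """Fractions of variance explained for a standard (non-varying) fit.

    The total is the sum of every fixed-term post-hoc variance, every
    random-term variance and the residual variance; the intercept
    contributes nothing.  A zero total (constant gene) yields an
    all-residual row flagged ``degenerate``.
    """
    comps = _components(fit, designs)
    total = sum(comps.values()) + fit.var_resid
    flags = [] if fit.converged else ["not_converged"]
    if total <= 0:
        fr = {t: 0.0 for t in comps}
        fr["residual"] = 1.0
        return PartitionRow(fr, sums_to_one=True, flags=flags + ["degenerate"])
    fr = {t: v / total for t, v in comps.items()}
    fr["residual"] = fit.var_resid / total
    return PartitionRow(fr, sums_to_one=True, flags=flags)


def icc(fit: FitResult, term: str, designs: DesignBundle | None = None) -> float:
    """Intra-class correlation for a random term.

    Equals that term's fraction of the total variance: the correlation
    between two observations sharing the term's level, which is 0 for
    observations from different levels.  When the fit carries fixed terms,
    pass ``designs`` so their post-hoc variances enter the denominator.
    """
    if term not in fit.var_random:
        raise KeyError(f"'{term}' is not a random term of this fit")
    if designs is not None:
        return partition_fractions(fit, designs)[term]
    if any(np.any(b != 0) for b in fit.beta.values()):
        raise ValueError(
            "icc on fits with non-null fixed terms needs the design bundle"
        )
    total = sum(fit.var_random.values()) + fit.var_resid
    if total <= 0:
        return 0.0
    return fit.var_random[term] / total


def partition_varying(fit: FitResult, designs: DesignBundle) -> PartitionRow:
    """Subset-specific fractions for a varying-coefficient fit.

    Each varying block (e.g. individual within one cell type) is divided by
    its subset's total variance.  Shared terms and the residual are reported
    against the global total.  A stratifier level whose grouping factor has
    no replicated levels cannot separate that component from noise; its
    fraction is NaN and flagged not-estimable.
    """
    if not designs.varying_parent:
        raise ValueError("fit has no varying-coefficient terms")
    flags = [] if fit.converged else ["not_converged"]
    shared_random = {
        t: v for t, v in fit.var_random.items() if t not in designs.varying_parent
    }
    fixed_global = {
        t: fixed_effect_variance(designs.fixed_encoding(t), fit.beta[t])
        for t in fit.beta
    }
    # global total: sample-size-weighted varying contributions
    n = designs.n_samples
    varying_avg = 0.0
    for t in designs.varying_parent:
        m = designs.subset_masks[t]
        varying_avg += fit.var_random[t] * (m.sum() / n)
    total = (
        sum(fixed_global.values())
        + sum(shared_random.values())
        + varying_avg
        + fit.var_resid
    )
    fr: dict[str, float] = {}
    for t, v in fixed_global.items():
        fr[t] = v / total if total > 0 else 0.0
    for t, v in shared_random.items():
        fr[t] = v / total if total > 0 else 0.0
    for t in designs.varying_parent:
        mask = designs.subset_masks[t]
        Zb = designs.Z[t][mask]
        counts = Zb.sum(axis=0)
        if not np.any(counts >= 2):
            fr[t] = float("nan")
            flags.append(f"not_estimable:{t}")
            continue
        sub_total = fit.var_random[t] + sum(shared_random.values()) + fit.var_resid
        for ft, b in fit.beta.items():
            sub_total += fixed_effect_variance(
                designs.fixed_encoding(ft), b, subset=mask
            )
        fr[t] = fit.var_random[t] / sub_total if sub_total > 0 else 0.0
    fr["residual"] = fit.var_resid / total if total > 0 else 1.0
    return PartitionRow(fr, sums_to_one=False, flags=flags)


@dataclass
class PartitionTable:
    """Genes × (terms + residual) table of variance fractions."""

    data: pd.DataFrame  # one row per gene, one column per term + residual
    sums_to_one: bool = True
    flags: dict[str, list[str]] = field(default_factory=dict)
    model: str = ""

    @classmethod
    def from_rows(
        cls, rows: dict[str, PartitionRow], model: str = ""
    ) -> "PartitionTable":
        if not rows:
            raise ValueError("no rows to assemble")
        first = next(iter(rows.values()))
        terms = first.terms
        for g, r in rows.items():
            if r.terms != terms:
                raise ValueError(f"gene '{g}' has a different term set")
        df = pd.DataFrame.from_dict(
            {g: r.fractions for g, r in rows.items()}, orient="index"
        )[list(terms)]
        df.index.name = "gene"
        flags = {g: r.flags for g, r in rows.items() if r.flags}
        return cls(
            data=df,
            sums_to_one=all(r.sums_to_one for r in rows.values()),
            flags=flags,
            model=model,
        )

    @property
    def terms(self) -> list[str]:
        return list(self.data.columns)

    def clean(self) -> pd.DataFrame:
        """Rows without degenerate/not-converged flags (used for medians)."""
        bad = {
            g
            for g, fl in self.flags.items()
            if any(f.startswith(("degenerate", "not_converged")) for f in fl)
        }
        return self.data.loc[[g for g in self.data.index if g not in bad]]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# varipart variance fractions; model: {self.model}\n")
            fh.write(f"# sums_to_one: {self.sums_to_one}\n")
            self.data.to_csv(fh)

    @classmethod
    def read_csv(cls, path) -> "PartitionTable":
        model, sums = "", True
        with open(path) as fh:
            text = fh.read()
        body = []
        for line in text.splitlines():
            if line.startswith("#"):
                if "model:" in line:
                    model = line.split("model:", 1)[1].strip()
                if "sums_to_one:" in line:
                    sums = line.split(":", 1)[1].strip() == "True"
            else:
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)), index_col=0)
        return cls(data=df, sums_to_one=sums, model=model)
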