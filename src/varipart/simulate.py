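"""Synthetic expression data with known variance structure.

The generator emulates multi-factor transcriptome study designs: crossed
categorical factors (individual, lab, batch), factors that are invariant
properties of another factor (sex or ancestry of an individual — the
structure that makes fixed-effects ANOVA designs singular), nested factors
(library within lab), continuous covariates, optional subset-specific
cross-individual variance (varying-coefficient scenarios) and optional
heteroskedastic residuals with matching precision weights.

For each gene, per-level effects are drawn from a standard normal and the
contribution of each term is scaled so its variance matches a target
fraction of the (unit) total.  In ``"exact"`` mode contributions are
additionally made mutually uncorrelated and scaled to hit the targets
exactly in sample (so the realized decomposition equals the target one);
in ``"sampled"`` mode contributions are drawn at their expected variance
and realized fractions fluctuate as they would in nature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "VaryingSpec",
    "SimScenario",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_weights",
]


@dataclass(frozen=True)
class FactorSpec:
    """One categorical study-design factor.

    ``scheme`` controls how levels are assigned to samples:
    ``"balanced"`` (round-robin), ``"random"``, ``"nested-in:<parent>"``
    (each of this factor's levels belongs to one parent level) or
    ``"invariant-of:<parent>"`` (constant within each parent level, e.g.
    sex per individual).
    """

    name: str
    n_levels: int
    scheme: str = "balanced"


@dataclass(frozen=True)
class VaryingSpec:
    """Subset-specific cross-group variance.

    ``fractions`` maps each level of ``stratifier`` to the target fraction
    of that subset's variance explained by ``group`` (relative to that
    subset's total: the group component plus the residual)."""

    stratifier: str
    group: str
    fractions: dict[str, float]


@dataclass(frozen=True)
class SimScenario:
    n_samples: int
    factors: tuple[FactorSpec, ...]
    fractions: dict[str, object]  # name -> fraction, or (lo, hi) per-gene range
    n_genes: int = 100
    seed: int = 0
    continuous: tuple[str, ...] = ()
    varying: VaryingSpec | None = None
    mode: str = "exact"
    weight_slope: float | None = None
    eqtl_term: str | None = None
    baseline_mean: float = 8.0

    def __post_init__(self):
        if self.mode not in ("exact", "sampled"):
            raise ValueError(f"mode must be 'exact' or 'sampled', got {self.mode!r}")
        names = [f.name for f in self.factors] + list(self.continuous)
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor/covariate names")
        unknown = set(self.fractions) - set(names) - {"residual"}
        if unknown:
            raise ValueError(f"fraction targets for unknown terms: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Per-gene generating fractions and realized component variances."""

    fractions: pd.DataFrame  # genes x (terms + residual), generator targets
    realized: pd.DataFrame  # genes x (terms + residual), realized sample shares
    weights: pd.DataFrame | None = None  # precision weights when heteroskedastic
    has_eqtl: pd.Series | None = None
    varying_terms: tuple[str, ...] = ()


def _resolve_fraction(value, rng) -> float:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return float(rng.uniform(lo, hi))
    return float(value)


def _assign_levels(scenario: SimScenario, rng) -> pd.DataFrame:
    n = scenario.n_samples
    codes: dict[str, np.ndarray] = {}
    n_levels = {f.name: f.n_levels for f in scenario.factors}
    for f in scenario.factors:
        if f.n_levels < 2:
            raise ValueError(f"factor '{f.name}' needs >= 2 levels")
        if f.scheme == "balanced":
            codes[f.name] = np.arange(n) % f.n_levels
        elif f.scheme == "random":
            for _ in range(100):
                c = rng.integers(0, f.n_levels, n)
                if len(np.unique(c)) >= 2:
                    break
            codes[f.name] = c
        elif f.scheme.startswith("invariant-of:"):
            parent = f.scheme.split(":", 1)[1]
            if parent not in codes:
                raise ValueError(
                    f"factor '{f.name}' is invariant-of '{parent}', which must "
                    "be declared earlier"
                )
            if f.n_levels > n_levels[parent]:
                raise ValueError(
                    f"'{f.name}' has more levels ({f.n_levels}) than its "
                    f"parent '{parent}' ({n_levels[parent]})"
                )
            pmap = rng.permutation(n_levels[parent]) % f.n_levels
            codes[f.name] = pmap[codes[parent]]
        elif f.scheme.startswith("nested-in:"):
            parent = f.scheme.split(":", 1)[1]
            if parent not in codes:
                raise ValueError(
                    f"factor '{f.name}' is nested in '{parent}', which must "
                    "be declared earlier"
                )
            if f.n_levels < n_levels[parent]:
                raise ValueError(
                    f"nested factor '{f.name}' needs at least as many levels "
                    f"as its parent '{parent}'"
                )
            owner = np.arange(f.n_levels) % n_levels[parent]
            children = {
                p: np.flatnonzero(owner == p) for p in range(n_levels[parent])
            }
            c = np.empty(n, dtype=int)
            for i, p in enumerate(codes[parent]):
                opts = children[int(p)]
                c[i] = opts[rng.integers(0, len(opts))]
            codes[f.name] = c
        else:
            raise ValueError(f"unknown assignment scheme {f.scheme!r}")
    meta = pd.DataFrame(index=[f"s{i + 1:04d}" for i in range(n)])
    meta.index.name = "sample_id"
    for f in scenario.factors:
        meta[f.name] = [f"{f.name}{c + 1:03d}" for c in codes[f.name]]
    for name in scenario.continuous:
        meta[name] = rng.normal(size=n)
    return meta


def _level_mean_project(v: np.ndarray, codes: np.ndarray, L: int) -> np.ndarray:
    """Project a sample vector onto the span of a factor's indicators."""
    sums = np.bincount(codes, weights=v, minlength=L)
    counts = np.bincount(codes, minlength=L).astype(float)
    counts[counts == 0] = 1.0
    return (sums / counts)[codes]


def _orthogonalize(c: np.ndarray, prev: list[np.ndarray]) -> np.ndarray:
    if not prev:
        return c - c.mean()
    B = np.column_stack([p - p.mean() for p in prev])
    c = c - c.mean()
    keep = np.linalg.norm(B, axis=0) > 1e-12
    if keep.any():
        coef, *_ = np.linalg.lstsq(B[:, keep], c, rcond=None)
        c = c - B[:, keep] @ coef
    return c


def _scale_to(c: np.ndarray, target_var: float, what: str) -> np.ndarray:
    v = float(np.var(c, ddof=1))
    if v < 1e-14:
        raise ValueError(
            f"exact variance scaling infeasible for '{what}': contribution "
            "vanished after decorrelation (too few free levels)"
        )
    return c * np.sqrt(target_var / v)


def simulate_dataset(
    scenario: SimScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression, metadata, truth) for a scenario.

    Expression is genes × samples on a log-like continuous scale with unit
    per-gene total variance; metadata rows are samples.  Deterministic:
    the same scenario (including seed) reproduces byte-identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    meta = _assign_levels(scenario, rng)
    n = scenario.n_samples
    exact = scenario.mode == "exact"

    factor_codes: dict[str, np.ndarray] = {}
    factor_L: dict[str, int] = {}
    for f in scenario.factors:
        levels = sorted(meta[f.name].unique())
        lut = {lv: i for i, lv in enumerate(levels)}
        factor_codes[f.name] = np.array([lut[v] for v in meta[f.name]])
        factor_L[f.name] = len(levels)

    # component build order: continuous first (rigid, cannot be
    # decorrelated), then factors by ascending level count so that factors
    # with few free dimensions face the fewest decorrelation constraints
    comp_order = list(scenario.continuous) + sorted(
        (f.name for f in scenario.factors), key=lambda t: factor_L[t]
    )

    varying_terms: list[str] = []
    vmasks: dict[str, np.ndarray] = {}
    vcodes: dict[str, np.ndarray] = {}
    if scenario.varying is not None:
        vs = scenario.varying
        svals = meta[vs.stratifier].astype(str).to_numpy()
        for lv in sorted(set(svals)):
            short = lv
            t = f"{vs.group}|{vs.stratifier}={short}"
            varying_terms.append(t)
            vmasks[t] = svals == lv
            gl = sorted(meta[vs.group][vmasks[t]].unique())
            lut = {g: i for i, g in enumerate(gl)}
            vcodes[t] = np.array(
                [lut.get(v, -1) for v in meta[vs.group].astype(str)]
            )
    term_names = comp_order + varying_terms
    genes = [f"gene{i + 1}" for i in range(scenario.n_genes)]
    expr = np.empty((scenario.n_genes, n))
    frac_rows = []
    real_rows = []
    wmat = np.empty((scenario.n_genes, n)) if scenario.weight_slope is not None else None

    for gi in range(scenario.n_genes):
        targets = {
            t: _resolve_fraction(scenario.fractions.get(t, 0.0), rng)
            for t in comp_order
        }
        ssum = sum(targets.values())
        if ssum > 1 + 1e-9:
            raise ValueError(f"target fractions sum to {ssum:.3f} > 1")
        resid_f = _resolve_fraction(scenario.fractions["residual"], rng) if (
            "residual" in scenario.fractions
        ) else 1.0 - ssum
        if abs(ssum + resid_f - 1.0) > 1e-6 and "residual" in scenario.fractions:
            raise ValueError("factor fractions plus residual must sum to 1")

        contribs: list[np.ndarray] = []
        realized: dict[str, float] = {}
        for t in comp_order:
            ft = targets[t]
            if ft <= 0:
                realized[t] = 0.0
                continue
            if t in factor_codes:
                eff = rng.normal(size=factor_L[t])
                c = eff[factor_codes[t]]
            else:
                x = meta[t].to_numpy(dtype=float)
                sx = x.std()
                c = (x - x.mean()) / (sx if sx > 0 else 1.0)
                c *= np.sign(rng.normal()) or 1.0
            if exact:
                if t in factor_codes and contribs:
                    prev_proj = [
                        _level_mean_project(p, factor_codes[t], factor_L[t])
                        for p in contribs
                    ]
                    c = _orthogonalize(c, prev_proj)
                else:
                    c = c - c.mean()
                c = _scale_to(c, ft, t)
            else:
                # expected-variance draw: the population variance of the
                # contribution equals the target; realized variance varies
                c = c * np.sqrt(ft)
            contribs.append(c)
            realized[t] = float(np.var(c, ddof=1))
        for t in comp_order:
            if targets[t] <= 0:
                realized.setdefault(t, 0.0)

        # varying components: subset-specific group effects with variance
        # v_s = f_s * r / (1 - f_s) so that within-subset FVE equals f_s
        for t in varying_terms:
            lv = t.split("=", 1)[1]
            f_s = float(scenario.varying.fractions.get(lv, 0.0))
            mask = vmasks[t]
            if f_s <= 0:
                realized[t] = 0.0
                continue
            if f_s >= 1:
                raise ValueError(f"varying fraction for '{lv}' must be < 1")
            v_s = f_s * resid_f / (1.0 - f_s)
            gl = int(vcodes[t][mask].max()) + 1
            eff = rng.normal(size=gl)
            c = np.zeros(n)
            c[mask] = eff[vcodes[t][mask]]
            if exact:
                sub = c[mask]
                sub = sub - sub.mean()
                c[mask] = sub
                c[mask] = _scale_to(sub, v_s, t)
            else:
                c[mask] = eff[vcodes[t][mask]] * np.sqrt(v_s)
            contribs.append(c)
            realized[t] = float(np.var(c[mask], ddof=1))

        systematic = scenario.baseline_mean + rng.normal() + np.sum(contribs, axis=0) if (
            contribs
        ) else np.full(n, scenario.baseline_mean + rng.normal())

        e = rng.normal(size=n)
        if scenario.weight_slope is not None:
            z = systematic - systematic.mean()
            sd = max(z.std(), 1e-12)
            w = np.exp(scenario.weight_slope * z / sd)
            w /= np.exp(np.mean(np.log(w)))
            e = e / np.sqrt(w)
            if exact:
                e = e - e.mean()
                wv = float(np.sum(w * e**2) / (n - 1))
                e *= np.sqrt(resid_f / wv)
            else:
                e *= np.sqrt(resid_f)
            wmat[gi] = w
        elif varying_terms and exact:
            # per-subset exact residual variance so subset FVEs are exact
            for t in varying_terms:
                mask = vmasks[t]
                sub = e[mask]
                prev_sub = [c[mask] for c in contribs]
                sub = _orthogonalize(sub, prev_sub)
                e[mask] = _scale_to(sub, resid_f, "residual")
        elif exact:
            if resid_f > 0:
                e = _orthogonalize(e, contribs)
                e = _scale_to(e, resid_f, "residual")
            else:
                e = np.zeros(n)
        else:
            e *= np.sqrt(resid_f)
        realized["residual"] = float(np.var(e, ddof=1))

        expr[gi] = systematic + e
        row = {t: targets.get(t, 0.0) for t in comp_order}
        for t in varying_terms:
            row[t] = float(scenario.varying.fractions.get(t.split("=", 1)[1], 0.0))
        row["residual"] = resid_f
        frac_rows.append(row)
        real_rows.append(realized)

    cols = term_names + ["residual"]
    fr = pd.DataFrame(frac_rows, index=genes)[cols]
    rl = pd.DataFrame(real_rows, index=genes)[cols]
    expr_df = pd.DataFrame(expr, index=genes, columns=meta.index)
    expr_df.index.name = "gene"

    has_eqtl = None
    if scenario.eqtl_term is not None:
        f = fr[scenario.eqtl_term].to_numpy()
        pr = 0.05 + 0.9 * f
        has_eqtl = pd.Series(
            (rng.uniform(size=len(genes)) < pr).astype(int), index=genes,
            name="has_eqtl",
        )

    weights_df = None
    if wmat is not None:
        weights_df = pd.DataFrame(wmat, index=genes, columns=meta.index)

    truth = SyntheticTruth(
        fractions=fr,
        realized=rl,
        weights=weights_df,
        has_eqtl=has_eqtl,
        varying_terms=tuple(varying_terms),
    )
    return expr_df, meta, truth


def simulate_weights(
    expr: pd.DataFrame, slope: float, seed: int = 0, noise_sd: float = 0.0
) -> pd.DataFrame:
    """Precision weights monotone in expression magnitude.

    Weights are ``exp(slope * z)`` of the gene-wise standardized expression
    (slope 0 gives equal weights), normalised per gene to geometric mean 1;
    ``noise_sd`` adds optional lognormal jitter (seeded).
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    rng = np.random.default_rng(seed)
    X = expr.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (X - mu) / sd
    logw = slope * z
    if noise_sd > 0:
        logw = logw + rng.normal(scale=noise_sd, size=X.shape)
    logw -= logw.mean(axis=1, keepdims=True)
    return pd.DataFrame(np.exp(logw), index=expr.index, columns=expr.columns)
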