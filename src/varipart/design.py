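"""Model specifications and design matrices.

A study design is described by a :class:`ModelSpec` naming which metadata
columns enter the per-gene model as fixed effects, which as random effects,
and which pairs form varying-coefficient terms (a grouping factor whose
variance is allowed to differ across the levels of a stratifying factor,
e.g. cross-individual variance evaluated separately within each cell type).

:func:`build_design` turns a metadata table plus a spec into numeric
matrices: one dense matrix ``X_j`` per fixed term and one 0/1 indicator
matrix ``Z_k`` per random term (or per stratifier level of a varying term).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "parse_formula",
    "validate_spec",
    "build_design",
]

_RANDOM_RE = re.compile(r"^\(\s*1\s*\|\s*([A-Za-z_]\w*)\s*\)$")
_VARYING_RE = re.compile(r"^\(\s*([A-Za-z_]\w*)\s*\|\s*([A-Za-z_]\w*)\s*\)$")
_NAME_RE = re.compile(r"^[A-Za-z_]\w*$")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the per-gene model.

    Parameters
    ----------
    fixed
        Ordered names of fixed-effect covariates (categorical or continuous).
    random
        Ordered names of random-intercept covariates (categorical).
    varying
        Pairs ``(stratifier, group)``: the ``group`` factor gets an
        independent random intercept with a separate variance within each
        level of the categorical ``stratifier``.
    include_intercept
        Whether the fixed design carries a global intercept (default).
    """

    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    varying: tuple[tuple[str, str], ...] = ()
    include_intercept: bool = True

    def __post_init__(self):
        roles: list[str] = list(self.fixed) + list(self.random)
        roles += [g for _, g in self.varying]
        dupes = {t for t in roles if roles.count(t) > 1}
        if dupes:
            raise ValueError(
                f"covariate(s) used in more than one model role: {sorted(dupes)}"
            )

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.fixed) + tuple(self.random) + tuple(
            f"{g}|{s}" for s, g in self.varying
        )

    def formula(self) -> str:
        parts = list(self.fixed)
        parts += [f"(1|{t})" for t in self.random]
        parts += [f"({s}|{g})" for s, g in self.varying]
        if not self.include_intercept:
            parts.insert(0, "0")
        return " + ".join(parts) if parts else "1"


def parse_formula(formula: str) -> ModelSpec:
    """Parse a compact formula string into a :class:`ModelSpec`.

    Plain names are fixed effects, ``(1|term)`` random intercepts and
    ``(stratifier|group)`` varying-coefficient terms.  A leading ``~`` is
    accepted and ignored; ``0`` or ``-1`` drops the intercept.

    >>> parse_formula("ancestry + sex + (1|individual) + (1|lab)")
    ModelSpec(fixed=('ancestry', 'sex'), random=('individual', 'lab'), ...)
    """
    s = formula.strip().lstrip("~").strip()
    fixed: list[str] = []
    random: list[str] = []
    varying: list[tuple[str, str]] = []
    intercept = True
    if not s:
        return ModelSpec()
    for raw in s.split("+"):
        tok = raw.strip()
        if not tok:
            raise ValueError(f"empty term in formula {formula!r}")
        if tok in ("0", "-1"):
            intercept = False
            continue
        if tok == "1":
            continue
        m = _RANDOM_RE.match(tok)
        if m:
            random.append(m.group(1))
            continue
        m = _VARYING_RE.match(tok)
        if m:
            varying.append((m.group(1), m.group(2)))
            continue
        if _NAME_RE.match(tok):
            fixed.append(tok)
            continue
        raise ValueError(f"cannot parse term {tok!r} in formula {formula!r}")
    return ModelSpec(
        fixed=tuple(fixed),
        random=tuple(random),
        varying=tuple(varying),
        include_intercept=intercept,
    )


def is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col)


def _check_metadata(metadata: pd.DataFrame) -> list[str]:
    out = []
    if metadata.index.has_duplicates:
        dup = metadata.index[metadata.index.duplicated()].unique().tolist()
        out.append(f"duplicated sample ids: {dup[:5]}")
    return out


def validate_spec(metadata: pd.DataFrame, spec: ModelSpec) -> list[str]:
    """Check a spec against a metadata table.

    Returns a list of human-readable diagnostics; an empty list means the
    spec is usable with :func:`build_design`.  Checks: referenced columns
    exist and have no missing values, random/stratifier/grouping factors are
    categorical with at least two observed levels, no referenced column is
    constant, and the combined fixed-effect design has full column rank.
    """
    diags = _check_metadata(metadata)
    referenced = list(spec.fixed) + list(spec.random)
    for s, g in spec.varying:
        referenced += [s, g]
    for name in referenced:
        if name not in metadata.columns:
            diags.append(f"column '{name}' not found in metadata")
    ok = [c for c in dict.fromkeys(referenced) if c in metadata.columns]
    for name in ok:
        col = metadata[name]
        if col.isna().any():
            diags.append(f"column '{name}' has missing values")
        elif col.nunique() < 2:
            diags.append(f"term '{name}' has 1 level (constant column)")
    for name in spec.random:
        if name in metadata.columns and not is_categorical(metadata[name]):
            diags.append(f"random-effect term '{name}' must be categorical")
    for s, g in spec.varying:
        if s in metadata.columns and not is_categorical(metadata[s]):
            diags.append(f"varying-term stratifier '{s}' must be categorical")
        if g in metadata.columns and not is_categorical(metadata[g]):
            diags.append(f"varying-term group '{g}' must be categorical")
    if not diags and spec.fixed:
        X = _combined_fixed(metadata, spec)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            diags.append(
                "fixed-effect design is rank deficient (collinear terms): "
                + ", ".join(spec.fixed)
            )
    return diags


def _encode_fixed(col: pd.Series) -> np.ndarray:
    """Fixed-term encoding: continuous as-is; categorical treatment-coded
    with the first sorted level as reference."""
    if is_categorical(col):
        levels = sorted(map(str, col.unique()))
        vals = col.astype(str).to_numpy()
        return np.column_stack([(vals == lv).astype(float) for lv in levels[1:]])
    return col.to_numpy(dtype=float)[:, None]


def _indicator(col: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(map(str, col.unique()))
    vals = col.astype(str).to_numpy()
    Z = np.column_stack([(vals == lv).astype(float) for lv in levels])
    return Z, levels


def _combined_fixed(metadata: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    blocks = [_encode_fixed(metadata[t]) for t in spec.fixed]
    n = len(metadata)
    if spec.include_intercept:
        blocks.insert(0, np.ones((n, 1)))
    return np.hstack(blocks) if blocks else np.empty((n, 0))


@dataclass
class DesignBundle:
    """Numeric design matrices for one spec on one metadata table.

    ``X`` maps each fixed term to its n×p_j matrix (intercept held
    separately), ``Z`` maps each random term to its n×q_k 0/1 indicator.
    Varying-coefficient terms appear in ``Z`` as one block per stratifier
    level, named ``"group|stratifier=level"``; their rows are zero outside
    the corresponding subset, recorded in ``subset_masks``.
    """

    spec: ModelSpec
    sample_ids: list[str]
    X: dict[str, np.ndarray]
    Z: dict[str, np.ndarray]
    z_levels: dict[str, list[str]]
    intercept: bool
    varying_parent: dict[str, tuple[str, str]] = field(default_factory=dict)
    subset_masks: dict[str, np.ndarray] = field(default_factory=dict)
    _fixed_alt: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return tuple(self.X)

    @property
    def random_terms(self) -> tuple[str, ...]:
        return tuple(self.Z)

    def combined_fixed(self) -> np.ndarray:
        """Intercept (if any) followed by every fixed-term block."""
        blocks = [self.X[t] for t in self.X]
        if self.intercept:
            blocks.insert(0, np.ones((self.n_samples, 1)))
        return np.hstack(blocks) if blocks else np.empty((self.n_samples, 0))

    def fixed_encoding(self, term: str) -> np.ndarray:
        """Design matrix used when *term* is treated as a fixed effect.

        For declared fixed terms this is ``X[term]``; for random terms it is
        the reference-coded (first level dropped) version of ``Z[term]``,
        which is what the OLS/ANOVA comparator fits.
        """
        if term in self.X:
            return self.X[term]
        if term in self._fixed_alt:
            return self._fixed_alt[term]
        if term in self.Z:
            return self.Z[term][:, 1:]
        raise KeyError(f"unknown term '{term}'")


def build_design(metadata: pd.DataFrame, spec: ModelSpec) -> DesignBundle:
    """Build fixed and random design matrices for *spec*.

    Raises ``ValueError`` if :func:`validate_spec` reports any diagnostic.
    Sample order follows the metadata row order; rows of every matrix are
    aligned to ``metadata.index``.
    """
    diags = validate_spec(metadata, spec)
    if diags:
        raise ValueError(
            "model spec has outstanding diagnostics:\n  " + "\n  ".join(diags)
        )
    X = {t: _encode_fixed(metadata[t]) for t in spec.fixed}
    Z: dict[str, np.ndarray] = {}
    z_levels: dict[str, list[str]] = {}
    varying_parent: dict[str, tuple[str, str]] = {}
    subset_masks: dict[str, np.ndarray] = {}
    for t in spec.random:
        Z[t], z_levels[t] = _indicator(metadata[t])
    for strat, group in spec.varying:
        svals = metadata[strat].astype(str).to_numpy()
        for lv in sorted(set(svals)):
            mask = svals == lv
            gcol = metadata[group][mask]
            glevels = sorted(map(str, gcol.unique()))
            gvals = metadata[group].astype(str).to_numpy()
            block = np.zeros((len(metadata), len(glevels)))
            for j, gl in enumerate(glevels):
                block[:, j] = mask & (gvals == gl)
            name = f"{group}|{strat}={lv}"
            Z[name] = block
            z_levels[name] = glevels
            varying_parent[name] = (strat, group)
            subset_masks[name] = mask
    return DesignBundle(
        spec=spec,
        sample_ids=[str(i) for i in metadata.index],
        X=X,
        Z=Z,
        z_levels=z_levels,
        intercept=spec.include_intercept,
        varying_parent=varying_parent,
        subset_masks=subset_masks,
    )


def align_expression(expr: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Reorder expression columns (samples) to match metadata rows by id.

    Alignment is by sample id only, never by position; any mismatch between
    the two id sets is a hard error listing the disagreement.
    """
    expr_ids = set(map(str, expr.columns))
    meta_ids = set(map(str, metadata.index))
    if expr_ids != meta_ids:
        only_e = sorted(expr_ids - meta_ids)[:10]
        only_m = sorted(meta_ids - expr_ids)[:10]
        raise ValueError(
            "expression and metadata sample ids disagree; "
            f"only in expression: {only_e}; only in metadata: {only_m}"
        )
    return expr.loc[:, [str(i) for i in metadata.index]]
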