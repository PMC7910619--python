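"""Tables as element descriptors and compositional descriptors for compounds.

Any finished table assigns element n the latent coordinate u_{k(n)}; those
coordinates form a low-dimensional element descriptor.  For a compound S
with atomic fractions w_1(S), ..., w_N(S) the compositional descriptor is
the fraction-weighted average

    phi(S) = sum_n w_n(S) u_{k(n)},

a convex combination of element coordinates, usable as a regression
feature for materials-property prediction.  Descriptors are benchmarked by
k-fold cross-validated regression (random forest by default) on a
formulas-plus-targets table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.manifold import TSNE
from sklearn.metrics import mean_absolute_error, mean_squared_error
from sklearn.model_selection import KFold

from ._elements import GROUP, KNOWN_SYMBOLS, PERIOD, SYMBOLS_H_TO_XE
from .assignment import ElementTable
from .errors import CoverageError, FormulaParseError, ParameterError
from .model import FeatureMatrix

__all__ = [
    "Composition",
    "parse_formula",
    "composition_descriptor",
    "standard_table",
    "pca_table",
    "tsne_table",
    "builtin_tables",
    "evaluate_descriptor",
]


@dataclass(frozen=True)
class Composition:
    """Normalized atomic fractions of a compound."""

    weights: dict

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ParameterError("composition weights must sum to 1")
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ParameterError("weights must lie in [0, 1]")

    @property
    def elements(self):
        return sorted(self.weights)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)|(\()|(\))(\d*\.?\d*)")


def parse_formula(formula: str) -> Composition:
    """Parse a Hill-style formula ("Fe2O3", "Li0.5CoO2", "Ca(OH)2").

    Subscripts may be integers or decimals; parenthesised groups are
    supported.  Counts are normalized to atomic fractions.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaParseError("empty formula")
    formula = formula.strip()
    stack = [{}]
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos:
            raise FormulaParseError(f"malformed formula {formula!r} at position {pos}")
        sym, count, lparen, rparen, group_count = m.groups()
        if sym:
            if sym not in KNOWN_SYMBOLS:
                raise FormulaParseError(f"unknown element symbol {sym!r} in {formula!r}")
            n = float(count) if count else 1.0
            if n <= 0:
                raise FormulaParseError(f"non-positive subscript in {formula!r}")
            stack[-1][sym] = stack[-1].get(sym, 0.0) + n
        elif lparen:
            stack.append({})
        else:  # rparen
            if len(stack) == 1:
                raise FormulaParseError(f"unbalanced ')' in {formula!r}")
            mult = float(group_count) if group_count else 1.0
            group = stack.pop()
            for s, n in group.items():
                stack[-1][s] = stack[-1].get(s, 0.0) + n * mult
        pos = m.end()
    if len(stack) != 1:
        raise FormulaParseError(f"unbalanced '(' in {formula!r}")
    counts = stack[0]
    if not counts:
        raise FormulaParseError(f"no elements found in {formula!r}")
    total = sum(counts.values())
    return Composition({s: n / total for s, n in counts.items()})


def composition_descriptor(comp: Composition, table: ElementTable) -> np.ndarray:
    """phi(S): fraction-weighted average of element coordinates."""
    cmap = table.coordinate_map()
    missing = [s for s in comp.weights if s not in cmap]
    if missing:
        raise CoverageError(missing)
    return sum(w * cmap[s] for s, w in comp.weights.items())


def standard_table() -> ElementTable:
    """The conventional periodic table as (group, period) integer coordinates,
    hydrogen through xenon.  Coordinates are raw group/period numbers, not
    rescaled to [-1, 1]; node ids are atomic numbers."""
    coords = np.array(
        [[GROUP[s], PERIOD[s]] for s in SYMBOLS_H_TO_XE], dtype=float
    )
    return ElementTable(
        labels=SYMBOLS_H_TO_XE,
        node_ids=np.arange(1, 55),
        coords=coords,
        provenance={"source": "standard periodic table (group, period)"},
    )


def pca_table(features: FeatureMatrix, n_components: int = 2) -> ElementTable:
    """2-D PCA coordinates of the items, packaged as a descriptor table."""
    scores = PCA(n_components=n_components).fit_transform(features.X)
    return ElementTable(
        labels=features.item_labels,
        node_ids=np.arange(features.N),
        coords=scores,
        provenance={"source": f"PCA({n_components})"},
    )


def tsne_table(features: FeatureMatrix, seed: int = 0, perplexity: float = 15.0) -> ElementTable:
    """2-D t-SNE coordinates of the items, packaged as a descriptor table."""
    emb = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=min(perplexity, max(2.0, features.N / 4)),
        init="pca",
    ).fit_transform(features.X)
    return ElementTable(
        labels=features.item_labels,
        node_ids=np.arange(features.N),
        coords=emb,
        provenance={"source": "t-SNE", "seed": seed},
    )


def builtin_tables(features: FeatureMatrix | None = None, seed: int = 0) -> dict:
    """Registry of reference descriptor tables.

    Always contains ``standard``; with a feature matrix supplied, also
    ``pca`` and ``tsne``.  PTG-produced tables can be merged in by the
    caller under any name.
    """
    registry = {"standard": standard_table()}
    if features is not None:
        registry["pca"] = pca_table(features)
        registry["tsne"] = tsne_table(features, seed=seed)
    return registry


def _require(features, name):
    if features is None:
        raise ParameterError(f"{name} coordinates require a feature matrix")


def evaluate_descriptor(
    formulas,
    targets,
    table: ElementTable,
    folds: int = 5,
    seed: int = 0,
    regressor=None,
) -> dict:
    """k-fold cross-validated regression of a property on phi(S).

    Coverage failures (formulas using elements the table lacks) are raised
    before any fitting.  Returns overall and per-fold MAE/RMSE; the fold
    partition depends only on (n_samples, folds, seed).
    """
    formulas = list(formulas)
    targets = np.asarray(targets, dtype=float)
    if len(formulas) != len(targets):
        raise ParameterError("formulas and targets must align")
    if len(formulas) < folds:
        raise ParameterError("need at least `folds` samples")

    comps = [parse_formula(f) for f in formulas]
    cmap = table.coordinate_map()
    missing = sorted(
        {s for c in comps for s in c.weights if s not in cmap}
    )
    if missing:
        raise CoverageError(missing)
    Phi = np.vstack([composition_descriptor(c, table) for c in comps])

    if regressor is None:
        regressor = RandomForestRegressor(random_state=seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mae, fold_rmse = [], []
    for train, test in kf.split(Phi):
        import sklearn.base

        model = sklearn.base.clone(regressor)
        model.fit(Phi[train], targets[train])
        pred = model.predict(Phi[test])
        fold_mae.append(mean_absolute_error(targets[test], pred))
        fold_rmse.append(float(np.sqrt(mean_squared_error(targets[test], pred))))
    return {
        "mae": float(np.mean(fold_mae)),
        "rmse": float(np.mean(fold_rmse)),
        "fold_mae": [float(v) for v in fold_mae],
        "fold_rmse": [float(v) for v in fold_rmse],
        "folds": folds,
        "seed": seed,
        "regressor": type(regressor).__name__,
        "regressor_params": getattr(regressor, "get_params", dict)(),
    }
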