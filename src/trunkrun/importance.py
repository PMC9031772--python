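"""PCA-propagated feature importance for the logistic risk models.

A fitted logistic model acts on selected principal components, each a linear
combination of the post-encoding standardized features. Composing the two
linear maps gives the sensitivity of the log-odds of injury to each feature:

    importance_f = | sum_i  w_i * PC_if |

with ``w_i`` the logistic coefficient of selected component ``i`` and
``PC_if`` the loading of feature ``f`` in that component. The absolute value
keeps the size of the influence and discards its sign, so opposing
contributions through different components can cancel — by design.

Because single-feature importances are numerous and noisy, they are
summarized per feature category (direction of the source axis, type of
feature, or both): the category value is the mean importance of its members,
normalized across categories to a proportion summing to one. The mean (not
the sum) compensates for categories holding different numbers of features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .features import FeatureDef, FeatureTable
from .modeling import RiskModel

__all__ = [
    "LinearModelDecomposition",
    "CategoryScheme",
    "decompose_lr",
    "feature_importance",
    "assign_categories",
    "category_importance",
    "fold_mean_importance",
]

SCHEME_KINDS = ("direction", "type", "combined")


@dataclass
class LinearModelDecomposition:
    """Logistic coefficients over selected components plus their loadings.

    ``w`` has one entry per selected component; ``loadings`` is the (k, m)
    matrix of component coefficients over the m post-encoding standardized
    features named by ``feature_names``.
    """

    w: np.ndarray
    loadings: np.ndarray
    feature_names: list

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        self.loadings = np.asarray(self.loadings, float)
        if self.loadings.ndim != 2 or self.loadings.shape[0] != len(self.w):
            raise ValueError(
                f"loadings shape {self.loadings.shape} inconsistent with {len(self.w)} coefficients"
            )
        if self.loadings.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.loadings.shape[1]} loading columns vs {len(self.feature_names)} feature names"
            )


def decompose_lr(model: RiskModel) -> LinearModelDecomposition:
    """Extract the linear decomposition from a fitted logistic ``RiskModel``."""
    if model.algorithm != "LR":
        raise ValueError("importance is defined for the interpretable LR models only")
    pipe = model.pipeline_
    names = list(pipe.named_steps["encode"].get_feature_names_out())
    pca = pipe.named_steps["pca"]
    support = pipe.named_steps["select"].get_support()
    w = pipe.named_steps["clf"].coef_.ravel()
    return LinearModelDecomposition(
        w=w, loadings=pca.components_[support], feature_names=names
    )


def feature_importance(decomp: LinearModelDecomposition) -> pd.Series:
    """Per-feature importance: |sum over components of w_i * PC_if|."""
    values = np.abs(decomp.w @ decomp.loadings)
    return pd.Series(values, index=decomp.feature_names, name="importance")


@dataclass
class CategoryScheme:
    """A total assignment of features to categories under one criterion."""

    kind: str
    mapping: dict  # feature name -> category label

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}; expected one of {SCHEME_KINDS}")

    @property
    def categories(self) -> list:
        return sorted(set(self.mapping.values()))


def _base_feature(encoded_name: str, defs: Mapping[str, FeatureDef]) -> str:
    """Map a post-encoding column name back to its source feature.

    One-hot columns are named ``<feature>_<level>`` by the encoder; numeric
    columns keep their name.
    """
    if encoded_name in defs:
        return encoded_name
    for name in defs:
        if encoded_name.startswith(name + "_"):
            return name
    raise KeyError(f"cannot map encoded column {encoded_name!r} to a known feature")


def assign_categories(
    defs: Union[Mapping[str, FeatureDef], FeatureTable],
    kind: str,
    feature_names: Optional[Sequence[str]] = None,
) -> CategoryScheme:
    """Build a category scheme from feature tags.

    ``kind`` is ``direction`` (ML/AP/VT/Res/ND), ``type``
    (sport/stat/quest) or ``combined`` (type_direction pairs actually
    present). ``feature_names`` may list post-encoding column names (one-hot
    columns inherit the tags of their source feature); by default the raw
    feature names are used.
    """
    if isinstance(defs, FeatureTable):
        defs = defs.defs
    names = list(feature_names) if feature_names is not None else list(defs)
    mapping = {}
    for n in names:
        d = defs[_base_feature(n, defs)]
        if kind == "direction":
            mapping[n] = d.direction
        elif kind == "type":
            mapping[n] = d.ftype
        elif kind == "combined":
            mapping[n] = f"{d.ftype}_{d.direction}"
        else:
            raise ValueError(f"unknown scheme kind {kind!r}")
    return CategoryScheme(kind=kind, mapping=mapping)


def category_importance(importances: pd.Series, scheme: CategoryScheme) -> pd.Series:
    """Relative average importance per category (proportions summing to 1).

    Each category's raw score is the mean importance of its member features;
    scores are then divided by their grand total. Categories without members
    among ``importances`` are omitted with a warning.
    """
    groups: dict[str, list] = {}
    for name, value in importances.items():
        if name not in scheme.mapping:
            raise KeyError(f"feature {name!r} is not categorized by the scheme")
        groups.setdefault(scheme.mapping[name], []).append(value)
    empty = set(scheme.categories) - set(groups)
    if empty:
        warnings.warn(f"categories without member features omitted: {sorted(empty)}")
    means = pd.Series({c: float(np.mean(v)) for c, v in groups.items()}, name="relative_average_importance")
    total = means.sum()
    if total == 0:
        raise ValueError("all importances are zero; proportions undefined")
    return (means / total).sort_index()


def fold_mean_importance(models: Sequence[RiskModel]) -> pd.Series:
    """Across-fold mean of per-feature importances of fitted LR models.

    Folds may disagree on the encoded feature set (e.g. a one-hot level
    absent from one training split); importances are aligned on the union,
    with absent features contributing zero in the folds that lack them.
    """
    per_fold = [feature_importance(decompose_lr(m)) for m in models]
    return pd.concat(per_fold, axis=1).fillna(0.0).mean(axis=1).rename("importance")
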