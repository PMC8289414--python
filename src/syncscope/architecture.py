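"""Nearest-neighbour contact-category probabilities.

Every unordered nearest-neighbour contact between typed endocrine cells
falls into exactly one of four categories:

* ``beta_homotypic`` — beta-beta,
* ``beta_heterotypic`` — beta with alpha or delta,
* ``alpha_delta_homotypic`` — alpha-alpha or delta-delta,
* ``alpha_delta_heterotypic`` — alpha-delta.

Probabilities are category counts divided by the total contact count,
so on a fully typed map the four probabilities sum to one exactly.
Group comparisons average islets (technical replicates) per mouse and
dispatch the per-mouse values (biological replicates) to the
statistical decision tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import ArchitectureMap
from .stats import TestReport, choose_and_run

CATEGORIES = (
    "beta_homotypic",
    "beta_heterotypic",
    "alpha_delta_homotypic",
    "alpha_delta_heterotypic",
)


@dataclass
class ContactProbabilities:
    """Per-islet contact-category probabilities and raw counts."""

    p_beta_homotypic: float
    p_beta_heterotypic: float
    p_alpha_delta_homotypic: float
    p_alpha_delta_heterotypic: float
    counts: dict[str, int]
    n_contacts: int

    def as_dict(self) -> dict[str, float]:
        return {
            "beta_homotypic": self.p_beta_homotypic,
            "beta_heterotypic": self.p_beta_heterotypic,
            "alpha_delta_homotypic": self.p_alpha_delta_homotypic,
            "alpha_delta_heterotypic": self.p_alpha_delta_heterotypic,
        }


def _categorize(type_a: str, type_b: str) -> str:
    a_beta, b_beta = type_a == "beta", type_b == "beta"
    if a_beta and b_beta:
        return "beta_homotypic"
    if a_beta or b_beta:
        return "beta_heterotypic"
    if type_a == type_b:
        return "alpha_delta_homotypic"
    return "alpha_delta_heterotypic"


def contact_probabilities(arch: ArchitectureMap) -> ContactProbabilities:
    """Classify every contact of an architecture and normalise to probabilities."""
    if len(arch.contacts) == 0:
        raise InputError("architecture has an empty contact graph")
    counts = {c: 0 for c in CATEGORIES}
    for a, b in arch.contacts:
        counts[_categorize(arch.types[a], arch.types[b])] += 1
    total = sum(counts.values())
    return ContactProbabilities(
        p_beta_homotypic=counts["beta_homotypic"] / total,
        p_beta_heterotypic=counts["beta_heterotypic"] / total,
        p_alpha_delta_homotypic=counts["alpha_delta_homotypic"] / total,
        p_alpha_delta_heterotypic=counts["alpha_delta_heterotypic"] / total,
        counts=counts,
        n_contacts=total,
    )


def per_mouse_means(
    islet_values: Sequence[float], mouse_ids: Sequence
) -> pd.Series:
    """Average technical replicates (islets) within each mouse."""
    if len(islet_values) != len(mouse_ids):
        raise InputError("islet values and mouse ids differ in length")
    s = pd.Series(list(islet_values), index=list(mouse_ids), dtype=float)
    return s.groupby(level=0).mean()


def compare_architectures(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> dict[str, TestReport]:
    """Per-category comparison of two cohorts of islet contact probabilities.

    Each group is a DataFrame with a ``mouse`` column and one column per
    contact category; islets are averaged per mouse before testing
    (mice are the biological replicates).  Needs >= 2 mice per group and
    >= 3 for the normality gate inside the decision tree.
    """
    for name, g in (("group_a", group_a), ("group_b", group_b)):
        if "mouse" not in g.columns:
            raise InputError(f"{name} lacks a 'mouse' column mapping islets to mice")
        if g["mouse"].nunique() < 2:
            raise InputError(f"{name} needs at least 2 mice")
    reports: dict[str, TestReport] = {}
    for cat in CATEGORIES:
        if cat not in group_a.columns or cat not in group_b.columns:
            raise InputError(f"missing category column {cat!r}")
        a = per_mouse_means(group_a[cat].to_numpy(), group_a["mouse"]).to_numpy()
        b = per_mouse_means(group_b[cat].to_numpy(), group_b["mouse"]).to_numpy()
        reports[cat] = choose_and_run(a, b)
    return reports
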