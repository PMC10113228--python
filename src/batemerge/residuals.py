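"""Residual ("weather-independent") activity and functional grouping.

The residual activity of a species is the partial effect of the
day-of-year smooth on the link scale: the component of modelled activity
that the weather covariates, the site factor and the diel cycle do not
explain.  Values near zero mean activity is driven by the measured
triggers; large absolute values indicate activity (or inactivity) on top
of what weather predicts.  Species are ranked by the median absolute
residual activity and partitioned into high/medium/low residual-activity
groups (HRA/MRA/LRA) guided by pairwise rank tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from .errors import DataError
from .gapm import FittedGAPM, predict

log = logging.getLogger(__name__)


@dataclass
class ResidualActivityCurve:
    """Link-scale DOY-smooth partial effect on a day grid (sum-to-zero)."""

    species: str
    doy_grid: np.ndarray
    value: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"doy": self.doy_grid, "value": self.value})


def residual_activity(
    fit: FittedGAPM,
    doy_grid=None,
    include_interaction: bool = False,
) -> ResidualActivityCurve:
    """Predicted activity as a function of DOY alone, on the link scale.

    By default only the DOY main-effect smooth is used ("DOY alone"); with
    ``include_interaction`` the ST-marginalized interaction is added.
    """
    grid = np.arange(0, 137) if doy_grid is None else np.asarray(doy_grid)
    newdata = pd.DataFrame({"DOY": grid.astype(float)})
    value = predict(fit, newdata, components=("f2",), scale="link")
    if include_interaction and "f3" in fit.blocks:
        # average the interaction over the diel cycle
        st_grid = np.linspace(-1.0, 1.0, 49)[:-1]
        tensor = fit.bases["f3"]
        vals = np.zeros(len(grid))
        for s in st_grid:
            vals += tensor.evaluate(np.full(len(grid), s), grid.astype(float)) \
                @ fit.coef[fit.blocks["f3"]]
        value = value + vals / len(st_grid)
    return ResidualActivityCurve(fit.species or "species", grid, value)


def median_abs_residual(curve: ResidualActivityCurve) -> float:
    """Median over the day grid of |residual activity|."""
    return float(np.median(np.abs(curve.value)))


@dataclass
class GroupAssignment:
    """Ranking, pairwise tests, compact letter display and HRA/MRA/LRA labels."""

    ranking: list[str]                  # decreasing median |residual activity|
    medians: dict
    p_matrix: pd.DataFrame              # Bonferroni-adjusted pairwise p-values
    letters: dict                       # species -> letter string, e.g. "ab"
    labels: dict                        # species -> HRA/MRA/LRA
    omnibus_p: float
    alpha: float = 0.05
    partition: list = field(default_factory=list)  # letter groups, ranked


def _letter_groups(species: list[str], ns_pairs: set) -> list[set]:
    """Greedy clique cover of the non-significant graph.

    Every non-significant pair ends up sharing at least one letter; no
    significant pair ever shares one (cliques contain only ns edges);
    isolated species get a singleton letter.
    """
    cliques: list[set] = []
    covered = set()
    for a, b in itertools.combinations(species, 2):
        key = tuple(sorted((a, b)))
        if key not in ns_pairs or key in covered:
            continue
        clique = {a, b}
        for c in species:
            if c in clique:
                continue
            if all(tuple(sorted((c, d))) in ns_pairs for d in clique):
                clique.add(c)
        cliques.append(clique)
        covered |= {tuple(sorted(p)) for p in itertools.combinations(clique, 2)}
    for s in species:
        if not any(s in c for c in cliques):
            cliques.append({s})
    # drop cliques fully contained in another (absorption)
    cliques = [c for c in cliques
               if not any(c < other for other in cliques)]
    return cliques


def classify_groups(
    curves: list[ResidualActivityCurve],
    alpha: float = 0.05,
    test: str = "mannwhitney",
) -> GroupAssignment:
    """Rank species by median |residual activity| and group them.

    Kruskal-Wallis omnibus over the per-day absolute curve values, then all
    pairwise two-sided Mann-Whitney tests with Bonferroni adjustment
    (p times the number of pairs, capped at 1).  Letters come from a greedy
    clique cover of the non-significant graph; HRA/MRA/LRA labels are
    assigned to the letter groups by rank thirds.
    """
    if len(curves) < 2:
        raise DataError("classify_groups needs at least 2 species")
    if test != "mannwhitney":
        raise DataError(f"unsupported pairwise test {test!r}")
    samples = {c.species: np.abs(c.value) for c in curves}
    species = list(samples)
    medians = {s: float(np.median(v)) for s, v in samples.items()}
    ranking = sorted(species, key=lambda s: -medians[s])

    omnibus_p = float(kruskal(*samples.values()).pvalue)

    n_pairs = len(species) * (len(species) - 1) // 2
    P = pd.DataFrame(np.ones((len(species), len(species))),
                     index=species, columns=species)
    ns_pairs = set()
    for a, b in itertools.combinations(species, 2):
        raw = float(mannwhitneyu(samples[a], samples[b],
                                 alternative="two-sided").pvalue)
        adj = min(1.0, raw * n_pairs)
        P.loc[a, b] = P.loc[b, a] = adj
        if adj >= alpha:
            ns_pairs.add(tuple(sorted((a, b))))

    groups = _letter_groups(ranking, ns_pairs)
    groups.sort(key=lambda g: min(ranking.index(s) for s in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {s: "" for s in species}
    for i, g in enumerate(groups):
        for s in g:
            letters[s] += alphabet[i % len(alphabet)]
    letters = {s: "".join(sorted(v)) for s, v in letters.items()}

    n_groups = len(groups)
    tier_names = ["HRA", "MRA", "LRA"]
    labels = {}
    for i, g in enumerate(groups):
        tier = tier_names[min(int(3 * i / n_groups), 2)] if n_groups >= 2 \
            else "MRA"
        for s in g:
            labels.setdefault(s, tier)
    return GroupAssignment(ranking, medians, P, letters, labels, omnibus_p,
                           alpha, partition=[set(g) for g in groups])
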