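"""Destructive hydrogen-bond detection from SEA tables.

The procedure quantifies, per variant m, how far its hydrogen-bond stability
vector sits from the wild type,

    D^m = sqrt( sum_i (SEA_i^m - SEA_i^WT)^2 ),

attributes the squared deviation to individual bonds,

    xi_j^m = (SEA_j^m - SEA_j^WT)^2 / (D^m)^2,

histograms the xi values per variant into nine 0.1-wide bins (table H),
clusters the H rows to find the variants whose deviation is concentrated in
few bonds, and finally defines "destructive" bonds as the rightmost tail of
the mean contribution xi_bar over those selected variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import stats
from .hbond_sea import HBondKey, SEATable
from .structure_io import annotate_position

logger = logging.getLogger(__name__)

CountingPolicy = Literal["union_bonds", "variant_present_bonds"]


@dataclass
class ContributionSet:
    """Per-variant deviations D^m and per-bond contributions xi_j^m."""

    D: pd.Series  # variant -> deviation >= 0
    xi: pd.DataFrame  # bonds x variants, each column sums to 1 (or 0 if D=0)
    sea: SEATable
    zero_variants: list[str] = field(default_factory=list)  # D == 0, xi all-zero

    @property
    def variants(self) -> list[str]:
        return list(self.D.index)


def compute_deviations(sea: SEATable) -> ContributionSet:
    """D^m and xi_j^m over the union bond set of a SEA table.

    Variants identical to the wild type (D = 0) get an all-zero xi column and
    are flagged rather than producing NaNs.
    """
    variants = sea.variants
    if not variants:
        raise ValueError("SEA table contains no variants besides the wild type")
    wt = sea.values[sea.wt_id].to_numpy()
    diff2 = (sea.values[variants].to_numpy() - wt[:, None]) ** 2
    d2 = diff2.sum(axis=0)
    d = np.sqrt(d2)
    xi = np.zeros_like(diff2)
    nz = d2 > 0
    xi[:, nz] = diff2[:, nz] / d2[nz]
    zero_variants = [v for v, ok in zip(variants, nz) if not ok]
    if zero_variants:
        logger.warning("variants identical to WT (D=0): %s", zero_variants)
    return ContributionSet(
        D=pd.Series(d, index=variants, name="D"),
        xi=pd.DataFrame(xi, index=sea.bonds, columns=variants),
        sea=sea,
        zero_variants=zero_variants,
    )


N_BINS = 9


@dataclass
class HTable:
    """Per-variant histogram of xi over nine bins of width 0.1.

    Bin i (1-based) covers [0.1*(i-1), 0.1*i) for i = 1..8; bin 9 closes the
    range as [0.8, 1.0] so that a bond carrying the entire deviation is
    counted.  ``counts`` is variants x 9.
    """

    counts: pd.DataFrame

    @property
    def variants(self) -> list[str]:
        return list(self.counts.index)

    def s_bar(self) -> pd.Series:
        """Mean of bins 2..9: tracks bonds contributing more than 10%."""
        return self.counts.iloc[:, 1:].mean(axis=1).rename("S_H")

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.index.name = "variant"
        df.to_csv(path, sep="\t")


def build_h_table(
    contrib: ContributionSet,
    counting_policy: CountingPolicy = "variant_present_bonds",
) -> HTable:
    """Histogram each variant's xi values into the 9-bin table H.

    Under ``variant_present_bonds`` only bonds observed in the variant or the
    wild type (SEA > 0 in either) enter that variant's row; ``union_bonds``
    counts every bond of the table.
    """
    edges = np.arange(0.0, 1.0, 0.1)  # left edges of bins 1..9 (bin 9 twice wide)
    rows = {}
    sea = contrib.sea
    wt = sea.values[sea.wt_id].to_numpy()
    for v in contrib.variants:
        xi = contrib.xi[v].to_numpy()
        if counting_policy == "variant_present_bonds":
            mask = (sea.values[v].to_numpy() > 0) | (wt > 0)
            xi = xi[mask]
        elif counting_policy != "union_bonds":
            raise ValueError(f"unknown counting policy {counting_policy!r}")
        idx = np.minimum(np.floor(xi / 0.1).astype(int), N_BINS - 1)
        rows[v] = np.bincount(idx, minlength=N_BINS)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=[f"H{i}" for i in range(1, 10)])
    return HTable(counts=counts)


def mean_sh(h: HTable, variant: str) -> float:
    """S_bar_H of one variant: mean of H-table cells 2..9."""
    if variant not in h.counts.index:
        raise KeyError(f"unknown variant {variant!r}")
    return float(h.counts.loc[variant].iloc[1:].mean())


def select_high_contribution_variants(
    h: HTable, bandwidth: float | None = None
) -> tuple[set[str], stats.ClusteringResult | None]:
    """Mean-shift the H rows and return variants of clusters with mean S_bar_H > 0.

    The clustering separates variants whose deviation from the wild type is
    spread thinly over many bonds (all xi < 0.1, S_bar_H = 0) from those with
    few dominating bonds.  A degenerate single-cluster outcome returns an
    empty selection with a warning.
    """
    if len(h.variants) < 2:
        raise ValueError("need >= 2 variants to cluster")
    points = h.counts.to_numpy(dtype=float)
    if bandwidth is None:
        try:
            bandwidth = stats.estimate_bandwidth(points)
        except ValueError:
            logger.warning("degenerate H rows (all identical); empty selection")
            return set(), None
    result = stats.mean_shift(points, bandwidth)
    if result.n_clusters < 2:
        logger.warning("mean-shift found a single cluster; empty selection")
        return set(), result
    sbar = h.s_bar().to_numpy()
    selected: set[str] = set()
    for c in range(result.n_clusters):
        members = result.members(c)
        if sbar[members].mean() > 0:
            selected.update(h.counts.index[members])
    return selected, result


@dataclass
class DestructiveResult:
    selected_variants: set[str]
    xi_bar: pd.Series  # bond -> mean contribution over selected variants
    threshold: float
    destructive_bonds: list[str]  # ordered by descending xi_bar
    explained_fraction: float

    def to_frame(self) -> pd.DataFrame:
        xb = self.xi_bar.loc[self.destructive_bonds]
        return pd.DataFrame(
            {"xi_bar": xb.values, "rank": np.arange(1, len(xb) + 1)},
            index=pd.Index(self.destructive_bonds, name="bond"),
        )


def detect_destructive(
    contrib: ContributionSet,
    selected: Iterable[str],
    tail: float = 0.05,
) -> DestructiveResult:
    """Tail-threshold the mean contribution over the selected variants.

    xi_bar_j is the mean of xi_j^m over the selected variants; the threshold
    is the empirical (1 - tail) quantile (linear interpolation) of the
    *nonzero* xi_bar values — bonds never deviating from the wild type form a
    point mass at zero that would otherwise dominate the quantile base.
    Destructive bonds are those with xi_bar >= threshold; the explained
    fraction is the mean over selected variants of the share of (D^m)^2 the
    destructive bonds carry.
    """
    selected = sorted(set(selected))
    if not selected:
        raise ValueError("empty variant selection")
    missing = [v for v in selected if v not in contrib.xi.columns]
    if missing:
        raise KeyError(f"unknown variants {missing}")
    if not 0 <= tail < 1:
        raise ValueError("tail must lie in [0, 1)")
    xi_bar = contrib.xi[selected].mean(axis=1).rename("xi_bar")
    if tail == 0:
        return DestructiveResult(set(selected), xi_bar, float("inf"), [], 0.0)
    base = xi_bar[xi_bar > 0]
    if base.empty:
        logger.warning("all mean contributions are zero; no destructive bonds")
        return DestructiveResult(set(selected), xi_bar, float("inf"), [], 0.0)
    threshold = float(np.quantile(base.to_numpy(), 1.0 - tail))
    mask = xi_bar >= threshold
    ordered = xi_bar[mask].sort_values(ascending=False)
    destructive = list(ordered.index)
    explained = float(contrib.xi.loc[destructive, selected].sum(axis=0).mean())
    return DestructiveResult(
        selected_variants=set(selected),
        xi_bar=xi_bar,
        threshold=threshold,
        destructive_bonds=destructive,
        explained_fraction=explained,
    )


def residues_of_bonds(
    bonds: Sequence[str | HBondKey],
) -> pd.DataFrame:
    """Unique (chain, residue) participants of a bond set, role-annotated.

    Returns a DataFrame with columns chain, residue, roles (comma-joined
    annotation roles of the per-subunit position).  Opaque bond labels that
    cannot be parsed are dropped with a warning.
    """
    residues: set[tuple[str, int]] = set()
    n_opaque = 0
    for b in bonds:
        if isinstance(b, str):
            try:
                b = HBondKey.from_string(b)
            except ValueError:
                n_opaque += 1
                continue
        residues.update(b.residues)
    if n_opaque:
        logger.warning("%d opaque bond labels skipped", n_opaque)
    rows = [
        {"chain": c, "residue": r, "roles": ",".join(annotate_position(r))}
        for c, r in sorted(residues)
    ]
    return pd.DataFrame(rows, columns=["chain", "residue", "roles"])
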