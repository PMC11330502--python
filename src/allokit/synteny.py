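"""Syntelog detection, NG86 Ks/Ka estimation, Ks-mode finding and dating.

Ks (synonymous substitutions per synonymous site) between homoeologous gene
pairs acts as a proxy clock: the mode of the Ks distribution marks a
duplication or divergence event, and anchoring one event of known age (for
grasses, the pan-Poales rho whole-genome duplication at roughly 70 Mya)
converts Ks to absolute time via T = Ks / (2r).
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from ._codons import (codon_sites, jukes_cantor, ng86_site_counts,
                      pathway_counts, validate_cds)
from .genome import Gene


@dataclass
class SyntelogPair:
    gene_a: str
    gene_b: str
    cds_a: str
    cds_b: str
    block: int
    orientation: str = "+"          # '+' collinear, '-' inverted
    ks: float | None = None
    ka: float | None = None


@dataclass
class KsDistribution:
    values: np.ndarray              # retained ks values (<= ks_filter_max)
    grid: np.ndarray
    density: np.ndarray
    modes: list[float]              # ascending
    heights: list[float]
    bandwidth: float
    ks_filter_max: float

    @property
    def primary_mode(self) -> float:
        i = int(np.argmax(self.heights))
        return self.modes[i]


@dataclass
class CalibratedClock:
    """Molecular clock from one calibration event: rate = Ks_cal / (2 T_cal)."""
    rate: float                     # substitutions/site/year
    ks_cal: float
    t_cal: float

    def date(self, ks: float) -> float:
        """Divergence time in years for a Ks value: T = ks / (2 rate)."""
        return ks / (2.0 * self.rate)


def calibrate(ks_cal: float, t_cal: float) -> CalibratedClock:
    if ks_cal <= 0 or t_cal <= 0:
        raise ValueError("calibration Ks and T must both be positive")
    return CalibratedClock(rate=ks_cal / (2.0 * t_cal), ks_cal=ks_cal, t_cal=t_cal)


def date(clock: CalibratedClock, ks: float) -> float:
    return clock.date(ks)


# ------------------------------------------------------------------ synteny
def _longest_increasing_chain(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing (i, j); patience sorting."""
    if not matches:
        return []
    matches = sorted(matches, key=lambda m: (m[0], -m[1]))
    tails: list[int] = []
    back: list[int] = []
    tail_idx: list[int] = []
    for idx, (_, j) in enumerate(matches):
        p = bisect_left(tails, j)
        if p == len(tails):
            tails.append(j)
            tail_idx.append(idx)
        else:
            tails[p] = j
            tail_idx[p] = idx
        back.append(tail_idx[p - 1] if p > 0 else -1)
    chain = []
    cur = tail_idx[len(tails) - 1]
    while cur != -1:
        chain.append(matches[cur])
        cur = back[cur]
    return chain[::-1]


def find_syntelogs(genes_x: list[Gene], genes_y: list[Gene],
                   min_block: int = 5) -> list[SyntelogPair]:
    """Chain collinear family matches into blocks of >= min_block pairs.

    Blocks are extracted greedily: the longest collinear chain (forward or
    inverted) is reported, its genes removed, and the search repeated until no
    chain reaches ``min_block``.  Pairing is one-to-one within blocks.
    """
    if not genes_x or not genes_y:
        raise ValueError("empty gene list")
    fam_y: dict[str, list[int]] = {}
    for j, g in enumerate(genes_y):
        fam_y.setdefault(g.family, []).append(j)
    matches = [(i, j) for i, gx in enumerate(genes_x)
               for j in fam_y.get(gx.family, ())]

    pairs: list[SyntelogPair] = []
    block_id = 0
    used_x: set[int] = set()
    used_y: set[int] = set()
    while True:
        live = [(i, j) for i, j in matches if i not in used_x and j not in used_y]
        fwd = _longest_increasing_chain(live)
        rev = _longest_increasing_chain([(i, -j) for i, j in live])
        chain, orient = (fwd, "+") if len(fwd) >= len(rev) else (
            [(i, -j) for i, j in rev], "-")
        if len(chain) < min_block:
            break
        block_id += 1
        for i, j in chain:
            used_x.add(i)
            used_y.add(j)
            pairs.append(SyntelogPair(
                gene_a=genes_x[i].gene_id, gene_b=genes_y[j].gene_id,
                cds_a=genes_x[i].cds, cds_b=genes_y[j].cds,
                block=block_id, orientation=orient))
    return pairs


# --------------------------------------------------------------------- NG86
@dataclass
class Ng86Result:
    ks: float                       # nan when Jukes-Cantor saturated
    ka: float
    ps: float
    pn: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def compute_ks(cds_a: str, cds_b: str) -> Ng86Result:
    """Nei–Gojobori (1986) Ks/Ka with Jukes–Cantor correction.

    Site counts are averaged between the two sequences; differences per codon
    are averaged over all mutational pathways that avoid stop codons.
    Sequences must be equal-length, gap-free and in frame.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length; codon-align first")
    validate_cds(cds_a, "first CDS")
    validate_cds(cds_b, "second CDS")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return Ng86Result(ks=jukes_cantor(ps), ka=jukes_cantor(pn), ps=ps, pn=pn,
                      syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd)


def attach_ks(pairs: list[SyntelogPair]) -> list[SyntelogPair]:
    for p in pairs:
        res = compute_ks(p.cds_a, p.cds_b)
        p.ks, p.ka = res.ks, res.ka
    return pairs


# ---------------------------------------------------------------- Ks modes
def ks_modes(ks_values, bandwidth: float = 0.02, ks_filter_max: float = 5.0,
             grid_step: float = 0.005, min_values: int = 30) -> KsDistribution:
    """Gaussian KDE on [0, ks_filter_max] (reflected at zero) and its modes.

    Modes are local density maxima at or above 10% of the global maximum;
    Ks values above ``ks_filter_max`` (synteny/annotation artifacts in real
    data) and undefined (saturated) values are excluded first.
    """
    vals = np.asarray([k for k in np.ravel(ks_values) if np.isfinite(k)], float)
    vals = vals[(vals >= 0) & (vals <= ks_filter_max)]
    if vals.size < min_values:
        raise ValueError(f"only {vals.size} usable Ks values (< {min_values})")
    grid = np.arange(0.0, ks_filter_max + grid_step / 2, grid_step)
    h = bandwidth
    z = (grid[:, None] - vals[None, :]) / h
    zr = (grid[:, None] + vals[None, :]) / h          # reflection at 0
    dens = (np.exp(-0.5 * z ** 2) + np.exp(-0.5 * zr ** 2)).sum(axis=1)
    dens /= vals.size * h * np.sqrt(2 * np.pi)

    peak = dens.max()
    modes, heights = [], []
    for i in range(dens.size):
        left = dens[i - 1] if i > 0 else -np.inf
        right = dens[i + 1] if i < dens.size - 1 else -np.inf
        if dens[i] > left and dens[i] >= right and dens[i] >= 0.1 * peak:
            modes.append(float(grid[i]))
            heights.append(float(dens[i]))
    order = np.argsort(modes)
    return KsDistribution(values=vals, grid=grid, density=dens,
                          modes=[modes[i] for i in order],
                          heights=[heights[i] for i in order],
                          bandwidth=h, ks_filter_max=ks_filter_max)
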