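"""Ploidy inference from the minor-allele-frequency (MAF) distribution.

At a heterozygous site the fraction of reads carrying the minor allele
reflects the number of homologous copies the reads collapse onto: two
effective copies put the peak at 0.5, three at 1/3.  For an allopolyploid
whose reads map uniquely to each subgenome, an allotetraploid therefore looks
functionally diploid (peak 0.4-0.5) while an allohexaploid peaks at 0.30-0.35.

Site filters follow the published protocol: total depth between 20 and 200,
minor-allele depth strictly greater than 7 (i.e. >= 8).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MAFProfile:
    maf: np.ndarray                 # folded MAF per retained site, in (0, 0.5]
    alt_fraction: np.ndarray        # unfolded alt/total, reported alongside
    grid: np.ndarray
    density: np.ndarray
    mode: float
    call: str                       # '4x', '6x' or 'ambiguous'
    bandwidth: float


def filter_sites(table: pd.DataFrame, min_total: int = 20, max_total: int = 200,
                 min_minor: int = 8) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the depth filters; returns (retained table, removal counts)."""
    total = table["ref_depth"] + table["alt_depth"]
    minor = np.minimum(table["ref_depth"], table["alt_depth"])
    low = total < min_total
    high = total > max_total
    weak = (~low) & (~high) & (minor < min_minor)
    keep = ~(low | high | weak)
    removed = {"below_min_total": int(low.sum()),
               "above_max_total": int(high.sum()),
               "minor_below_min": int(weak.sum())}
    return table[keep].reset_index(drop=True), removed


def maf_density(table: pd.DataFrame, bandwidth: float = 0.02,
                grid_step: float = 0.0025, min_sites: int = 200) -> MAFProfile:
    """Folded-MAF kernel density with reflection at both boundaries.

    MAF = min(ref, alt) / total, in (0, 0.5]; folding makes the call
    insensitive to reference-allele polarity.  The density is reflected at
    0.5 (and 0) so the mode of a peak sitting on the boundary is not shrunk
    inward.  The ploidy call takes the primary mode: [0.40, 0.50] ->
    allotetraploid-like '4x', [0.30, 0.35] -> allohexaploid-like '6x',
    anything else 'ambiguous'.
    """
    total = (table["ref_depth"] + table["alt_depth"]).to_numpy(float)
    if (total <= 0).any():
        raise ValueError("sites with zero depth; filter first")
    if len(table) < min_sites:
        raise ValueError(f"only {len(table)} sites (< {min_sites}); "
                         "MAF density would be unreliable")
    alt_fraction = table["alt_depth"].to_numpy(float) / total
    maf = np.minimum(alt_fraction, 1.0 - alt_fraction)

    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    h = bandwidth
    parts = []
    for reflected in (maf, -maf, 1.0 - maf):      # data, mirror at 0, mirror at 0.5
        z = (grid[:, None] - reflected[None, :]) / h
        parts.append(np.exp(-0.5 * z ** 2).sum(axis=1))
    dens = sum(parts) / (maf.size * h * np.sqrt(2 * np.pi))
    mode = float(grid[int(np.argmax(dens))])

    if 0.40 <= mode <= 0.50:
        call = "4x"
    elif 0.30 <= mode <= 0.35:
        call = "6x"
    else:
        call = "ambiguous"
    return MAFProfile(maf=maf, alt_fraction=alt_fraction, grid=grid,
                      density=dens, mode=mode, call=call, bandwidth=h)
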