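"""B-chromosome dosage from masked coverage ratios and origin tracing.

Copy number: mean read depth over unmasked 1-kb windows of the B chromosome
divided by the same mean over all other chromosomes.  Reads from the two-copy
main chromosomes set the baseline, so a ratio of ~1 means the B is present at
standard dosage, ~2 doubled, and <= 0.4 suggests the B is absent with only
residual mismapping.

Origin tracing: the B sequence is tiled into 300-bp fragments; each fragment
is seeded with exact 15-mer matches against the main chromosomes and extended
ungapped.  A fragment maps "primarily" if it has a unique best hit with
identity >= 0.8 over >= 50% of its length; the primary fraction bounds how
much of the B was sourced from the main genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, MaskInterval

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class CoverageTrack:
    windows: pd.DataFrame   # chrom, win_start, win_end, depth, mask (''/reason)

    def unmasked(self) -> pd.DataFrame:
        return self.windows[self.windows["mask"] == ""]


@dataclass
class BCopyEstimate:
    depth_b: float
    depth_rest: float
    ratio: float
    interpretation: str


@dataclass
class FragmentTrace:
    fragments: pd.DataFrame  # b_start, b_end, chrom, identity, coverage, primary
    n_fragments: int
    n_primary: int
    per_chromosome: dict[str, int] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_primary / self.n_fragments if self.n_fragments else 0.0

    @property
    def percent(self) -> float:
        """Primary-mapped fraction as a percentage, printed precision."""
        return round(100.0 * self.fraction, 2)


def window_coverage(depth: pd.DataFrame, masks: list[MaskInterval],
                    window: int = 1000,
                    artifact_tracks: dict[str, pd.DataFrame] | None = None,
                    artifact_fold: float = 3.0,
                    mask_fraction: float = 0.5) -> CoverageTrack:
    """Re-bin a depth table into fixed windows and flag masked windows.

    ``depth`` holds (chrom, win_start, win_end, depth) rows at any resolution
    dividing evenly into ``window``; a terminal short window is kept.  Windows
    with >= ``mask_fraction`` of their bases under a repeat/artifact mask are
    flagged with that mask class.  Additionally, windows whose depth exceeds
    ``artifact_fold`` x the genome-wide median in this track *and in every
    extra track supplied* (other sequenced lineages) are flagged 'artifact' —
    organelle insertions and assembly errors spike in all lineages at once.
    """
    tracks = {"self": depth, **(artifact_tracks or {})}
    binned = {name: _rebin(df, window) for name, df in tracks.items()}
    out = binned["self"].copy()
    out["mask"] = ""

    # interval masks: flag windows whose total masked fraction reaches
    # mask_fraction, by the mask class covering the most bases
    mask_by_chrom: dict[str, list[MaskInterval]] = {}
    for m in masks:
        mask_by_chrom.setdefault(m.chrom, []).append(m)
    for idx, row in out.iterrows():
        covered: dict[str, float] = {}
        for m in mask_by_chrom.get(row["chrom"], ()):
            ov = min(m.end, row["win_end"]) - max(m.start, row["win_start"])
            if ov > 0:
                covered[m.mask_class] = covered.get(m.mask_class, 0.0) + ov
        if covered:
            total = sum(covered.values()) / (row["win_end"] - row["win_start"])
            if total >= mask_fraction:
                out.at[idx, "mask"] = max(covered, key=covered.get)

    # cross-lineage high-depth artifact rule; the reference median is taken
    # over windows that survived repeat masking so collapsed repeats do not
    # drag it upward
    clean = (out["mask"] == "").to_numpy()
    spike = np.ones(len(out), dtype=bool)
    for name, df in binned.items():
        aligned = df.set_index(["chrom", "win_start"]).reindex(
            pd.MultiIndex.from_frame(out[["chrom", "win_start"]]))["depth"].to_numpy()
        med = float(np.median(aligned[clean]))
        spike &= aligned > artifact_fold * med
    out.loc[spike & (out["mask"] == ""), "mask"] = "artifact"
    return CoverageTrack(windows=out.reset_index(drop=True))


def _rebin(depth: pd.DataFrame, window: int) -> pd.DataFrame:
    rows = []
    for chrom, grp in depth.groupby("chrom", sort=True):
        grp = grp.sort_values("win_start")
        starts = grp["win_start"].to_numpy()
        ends = grp["win_end"].to_numpy()
        vals = grp["depth"].to_numpy(float)
        bases = vals * (ends - starts)
        bins = starts // window
        for b in np.unique(bins):
            sel = bins == b
            s, e = int(starts[sel].min()), int(ends[sel].max())
            rows.append((chrom, s, e, bases[sel].sum() / (e - s)))
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end", "depth"])


def b_copy_ratio(track: CoverageTrack, b_chromosome: str) -> BCopyEstimate:
    """Ratio of mean unmasked depth on the B versus all other chromosomes."""
    un = track.unmasked()
    on_b = un[un["chrom"] == b_chromosome]["depth"]
    rest = un[un["chrom"] != b_chromosome]["depth"]
    if on_b.empty or rest.empty:
        raise ValueError("need at least one unmasked window on each side")
    depth_b, depth_rest = float(on_b.mean()), float(rest.mean())
    ratio = depth_b / depth_rest if depth_rest > 0 else 0.0
    if ratio <= 0.4:
        note = ("B chromosome likely absent; residual depth consistent with "
                "mismapping")
    elif ratio >= 1.6:
        note = "B chromosome at elevated dosage (~{:.0f} copies vs 2-copy baseline)".format(
            round(2 * ratio))
    else:
        note = "B chromosome at standard dosage (~2 copies)"
    return BCopyEstimate(depth_b=depth_b, depth_rest=depth_rest,
                         ratio=ratio, interpretation=note)


# -------------------------------------------------------------- origin trace
def _codes(seq: str, k: int) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)].astype(np.int64)
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out += arr[i:i + n] << (2 * (k - 1 - i))
    return out


_RC = str.maketrans("ACGT", "TGCA")


def trace_origins(b_sequence: str, main_genome: AnnotatedGenome,
                  fragment: int = 300, min_identity: float = 0.8,
                  min_cov: float = 0.5, seed_k: int = 15,
                  max_diagonals: int = 25) -> FragmentTrace:
    """Tile the B into fragments and trace each against the main chromosomes.

    The terminal remainder is kept as a fragment when >= fragment/2 bp.
    Ties for the best hit (identical top identity on two locations) make a
    fragment non-primary: multi-copy sequence cannot be assigned an origin.
    """
    if fragment < 50:
        raise ValueError("fragment must be >= 50 bp")
    if not main_genome.chromosomes:
        raise ValueError("main genome is empty")

    chroms = sorted(main_genome.chromosomes)
    index_codes, index_pos, index_chrom, chrom_arrs = [], [], [], {}
    for ci, chrom in enumerate(chroms):
        seq = main_genome.chromosomes[chrom]
        chrom_arrs[chrom] = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        codes = _codes(seq, seed_k)
        index_codes.append(codes)
        index_pos.append(np.arange(codes.size, dtype=np.int64))
        index_chrom.append(np.full(codes.size, ci, dtype=np.int32))
    codes_all = np.concatenate(index_codes)
    pos_all = np.concatenate(index_pos)
    chrom_all = np.concatenate(index_chrom)
    order = np.argsort(codes_all, kind="stable")
    codes_all, pos_all, chrom_all = codes_all[order], pos_all[order], chrom_all[order]

    starts = list(range(0, len(b_sequence) - fragment + 1, fragment))
    tail = len(b_sequence) - (starts[-1] + fragment if starts else 0)
    if tail >= fragment / 2:
        starts.append(starts[-1] + fragment if starts else 0)

    rows = []
    per_chrom: dict[str, int] = {}
    n_primary = 0
    for s in starts:
        frag_seq = b_sequence[s:min(s + fragment, len(b_sequence))]
        hits = []
        for strand, fs in (("+", frag_seq), ("-", frag_seq.translate(_RC)[::-1])):
            frag_arr = _CODE[np.frombuffer(fs.encode(), dtype=np.uint8)]
            fcodes = _codes(fs, seed_k)
            if fcodes.size == 0:
                continue
            lo = np.searchsorted(codes_all, fcodes, side="left")
            hi = np.searchsorted(codes_all, fcodes, side="right")
            diag_keys = []
            for qi in range(fcodes.size):
                # skip seeds from high-copy repeats: they cannot localise
                if 0 < hi[qi] - lo[qi] <= 100:
                    for t in range(lo[qi], hi[qi]):
                        diag_keys.append((int(chrom_all[t]),
                                          int(pos_all[t]) - qi))
            if not diag_keys:
                continue
            uniq, counts = np.unique(np.array(diag_keys, dtype=np.int64).reshape(-1, 2),
                                     axis=0, return_counts=True)
            top = np.argsort(-counts)[:max_diagonals]
            for t in top:
                ci, offset = int(uniq[t, 0]), int(uniq[t, 1])
                chrom = chroms[ci]
                carr = chrom_arrs[chrom]
                a0 = max(0, offset)
                a1 = min(carr.size, offset + len(fs))
                if a1 <= a0:
                    continue
                q0, q1 = a0 - offset, a1 - offset
                matches = int((carr[a0:a1] == frag_arr[q0:q1]).sum())
                identity = matches / len(fs)
                cov = (a1 - a0) / len(fs)
                hits.append((identity, cov, chrom, a0, strand))
        e = min(s + fragment, len(b_sequence))
        best = None
        primary = False
        if hits:
            hits.sort(key=lambda h: -h[0])
            best = hits[0]
            unique_best = len(hits) == 1 or hits[1][0] < best[0]
            primary = (best[0] >= min_identity and best[1] >= min_cov
                       and unique_best)
        rows.append((s, e, best[2] if best else "", best[0] if best else 0.0,
                     best[1] if best else 0.0, primary))
        if primary:
            n_primary += 1
            per_chrom[best[2]] = per_chrom.get(best[2], 0) + 1
    df = pd.DataFrame(rows, columns=["b_start", "b_end", "chrom", "identity",
                                     "coverage", "primary"])
    return FragmentTrace(fragments=df, n_fragments=len(starts),
                         n_primary=n_primary, per_chromosome=per_chrom)
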