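"""Masked, filtered, fixed-size window alignments from consensus genomes.

Pseudohaploid consensus genomes are positionally homologous by construction
(every sample is called against the same reference), so windowing is pure
coordinate arithmetic: apply the repeat mask, cut consecutive non-overlapping
windows, drop windows where any sample is mostly missing, and count
parsimony-informative sites.  Coordinates are 0-based half-open throughout
(BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_LUT_N = np.frombuffer("ACGTN".encode(), dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("-")] = 4  # gaps are undefined here; treat as missing
_CODE[ord("n")] = 4


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A,C,G,T,N -> 0..4)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"invalid character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _LUT_N[codes].tobytes().decode()


@dataclass
class ConsensusGenome:
    """One sample's pseudohaploid genome over the alphabet {A,C,G,T,N}.

    Lowercase input is uppercased and gaps become 'N' on ingestion.
    """

    sample: str
    chromosomes: dict[str, str]

    def __post_init__(self):
        clean = {}
        for name, seq in self.chromosomes.items():
            if name in clean:
                raise ValueError(f"duplicate chromosome name {name!r}")
            clean[name] = decode(encode(seq))
        self.chromosomes = clean

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}


@dataclass
class MaskTrack:
    """Per-chromosome intervals to be flagged as missing (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self):
        for chrom, iv in self.intervals.items():
            iv = sorted((int(s), int(e)) for s, e in iv)
            for s, e in iv:
                if s < 0 or e < s:
                    raise ValueError(f"bad interval ({s},{e}) on {chrom}")
            self.intervals[chrom] = iv

    def total_masked(self) -> int:
        tot = 0
        for iv in self.intervals.values():
            last = -1
            for s, e in iv:
                s = max(s, last)
                tot += max(0, e - s)
                last = max(last, e)
        return tot


@dataclass
class WindowAlignment:
    """One genomic fragment: a multi-sample equal-length alignment slice."""

    chrom: str
    start: int
    end: int
    samples: list[str]
    matrix: np.ndarray  # (n_samples, end-start) uint8 codes

    def __post_init__(self):
        if self.matrix.shape != (len(self.samples), self.end - self.start):
            raise ValueError("matrix shape does not match samples/coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start

    def missing_fraction(self) -> dict[str, float]:
        frac = (self.matrix == 4).mean(axis=1)
        return {s: float(f) for s, f in zip(self.samples, frac)}

    def sequences(self) -> dict[str, str]:
        return {s: decode(self.matrix[i]) for i, s in enumerate(self.samples)}

    @classmethod
    def from_sequences(cls, seqs: dict[str, str], chrom: str = "chr1",
                       start: int = 0) -> "WindowAlignment":
        samples = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        (length,) = lengths
        matrix = np.stack([encode(seqs[s]) for s in samples])
        return cls(chrom, start, start + length, samples, matrix)


# ---------------------------------------------------------------------------
# operations


def apply_mask(g: ConsensusGenome, m: MaskTrack) -> ConsensusGenome:
    """Set every masked position to 'N'; idempotent."""
    out = {}
    for chrom, seq in g.chromosomes.items():
        codes = encode(seq)
        for s, e in m.intervals.get(chrom, []):
            if e > len(codes):
                raise ValueError(
                    f"interval ({s},{e}) beyond end of {chrom} ({len(codes)} bp)")
            codes[s:e] = 4
        out[chrom] = decode(codes)
    return ConsensusGenome(g.sample, out)


def split_windows(genomes: Sequence[ConsensusGenome],
                  window_size: int = 100_000) -> list[WindowAlignment]:
    """Cut consecutive non-overlapping windows; drop trailing remainders."""
    if window_size < 1:
        raise ValueError("window_size must be positive")
    ref = genomes[0].lengths()
    for g in genomes[1:]:
        if g.lengths() != ref:
            raise ValueError(
                f"chromosome names/lengths of {g.sample!r} differ from "
                f"{genomes[0].sample!r}")
    samples = [g.sample for g in genomes]
    windows = []
    for chrom, length in ref.items():
        stacked = np.stack([encode(g.chromosomes[chrom]) for g in genomes])
        for k in range(length // window_size):
            s, e = k * window_size, (k + 1) * window_size
            windows.append(WindowAlignment(chrom, s, e, list(samples),
                                           stacked[:, s:e].copy()))
    return windows


def filter_windows(ws: Sequence[WindowAlignment], max_missing: float = 0.60
                   ) -> tuple[list[WindowAlignment], pd.DataFrame]:
    """Drop windows where any sample is > max_missing 'N' (strict inequality).

    Returns the kept windows and a per-window report with the verdict and
    the offending samples.
    """
    kept, rows = [], []
    for w in ws:
        mf = w.missing_fraction()
        offending = sorted(s for s, f in mf.items() if f > max_missing)
        ok = not offending
        if ok:
            kept.append(w)
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "kept": ok, "offending_samples": ",".join(offending),
            "max_missing_fraction": max(mf.values()) if mf else 0.0,
        })
    return kept, pd.DataFrame(rows)


def count_informative_sites(w: WindowAlignment) -> int:
    """Parsimony-informative columns: >=2 states each carried by >=2 samples,
    evaluated on non-'N' residues."""
    counts = np.stack([(w.matrix == b).sum(axis=0) for b in range(4)])
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def window_manifest(ws: Sequence[WindowAlignment]) -> pd.DataFrame:
    """TSV-ready per-window summary (coordinates, informative sites, missing)."""
    rows = []
    for w in ws:
        row = {"chrom": w.chrom, "start": w.start, "end": w.end,
               "n_informative": count_informative_sites(w)}
        for s, f in w.missing_fraction().items():
            row[f"missing_{s}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
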