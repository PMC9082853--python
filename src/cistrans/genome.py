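"""Distance-independent ("trans") model of random intrachromosomal pairs.

A trans-QTL acts on its molecular trait through an intermediate gene, so the
distance between the lead variant and the cognate gene's transcription start
site (TSS) carries no signal: conditional on both positions landing on the
same chromosome, the pair is statistically indistinguishable from two
uniform random positions on that chromosome.  For a chromosome of length
``N`` the number of ordered position pairs at distance ``d`` (0 < d < N) is
``2 * (N - d)`` out of ``N**2``, i.e. a triangular density that is maximal at
``d = 1`` and reaches zero at ``d = N``.  Marginalising over chromosomes, a
random intrachromosomal pair falls on chromosome ``i`` with probability
``N_i**2 / sum(N_j**2)``, so the genome-wide density is the
chromosome-length-weighted mixture of per-chromosome triangles.

The model has no free parameters beyond the chromosome length table; the
default table covers the 23 chromosomes relevant to molecular-QTL mapping
(autosomes 1-22 plus X) using GRCh38 sequence lengths.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GRCH38_LENGTHS",
    "ChromosomeSet",
    "TransModel",
    "sample_trans",
]

#: GRCh38 primary-assembly sequence lengths, chr1-22 + chrX (bp).
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrX": 156_040_895,
}


@dataclass(frozen=True)
class ChromosomeSet:
    """An ordered, named table of chromosome lengths in base pairs."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    build: str = "custom"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(n <= 0 for n in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def lengths_bp(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @classmethod
    def default(cls) -> "ChromosomeSet":
        """The 23-chromosome human set (autosomes + X, GRCh38 lengths)."""
        return cls(
            names=tuple(GRCH38_LENGTHS),
            lengths=tuple(GRCH38_LENGTHS.values()),
            build="GRCh38",
        )

    @classmethod
    def from_mapping(cls, table: dict[str, int], build: str = "custom") -> "ChromosomeSet":
        return cls(names=tuple(table), lengths=tuple(int(v) for v in table.values()), build=build)

    @classmethod
    def from_table(cls, path: str | Path, build: str | None = None) -> "ChromosomeSet":
        """Read chromosome lengths from a two-column TSV or a .fai index.

        Accepts either a headered TSV with columns ``name`` and ``length_bp``
        (extra columns ignored) or a headerless samtools ``.fai`` layout whose
        first two columns are sequence name and length.
        """
        path = Path(path)
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            first = fh.readline()
            fields = first.rstrip("\n").split("\t")
            header = not (len(fields) >= 2 and fields[1].isdigit())
            if not header:
                names.append(fields[0])
                lengths.append(int(fields[1]))
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                names.append(fields[0])
                lengths.append(int(fields[1]))
        return cls(names=tuple(names), lengths=tuple(lengths),
                   build=build or path.stem)


class TransModel:
    """Distance distribution of two random positions on the same chromosome.

    Parameters
    ----------
    chromosomes:
        Chromosome length table; defaults to the human 23-chromosome set.

    Notes
    -----
    Densities are normalised so that the *discrete* mass over integer
    distances ``d = 1 .. max(N_i)`` sums to exactly 1 (the raw triangular
    mixture sums to ``sum N_i (N_i - 1) / sum N_i**2``, marginally below 1,
    because zero distances are excluded).  The correction is O(1/N) and
    matters only for the base-pair-scale toy genomes used in tests.
    """

    def __init__(self, chromosomes: ChromosomeSet | None = None):
        self.chromosomes = chromosomes if chromosomes is not None else ChromosomeSet.default()
        n = self.chromosomes.lengths_bp
        self._n = n
        self._sum_sq = float(np.sum(n ** 2))
        self.chromosome_weights = n ** 2 / self._sum_sq
        # discrete mass of the raw Eq.-style density over d = 1..max(N_i)
        self.normalization = float(np.sum(n * (n - 1))) / self._sum_sq
        self._pairs_total = float(np.sum(n * (n - 1)))
        self.max_length = float(n.max())
        self.log_max = float(np.log10(self.max_length))

    # ------------------------------------------------------------------ #
    # densities

    def density_linear(self, d):
        """Probability per bp of a random same-chromosome pair at distance d.

        Evaluates ``sum_i 2 (N_i - d) [d < N_i] / sum_i N_i**2``, renormalised
        so the discrete sum over d = 1..max(N_i) is exactly 1.  For integer
        ``d`` this equals the exact probability mass of distance ``d``.
        """
        d_arr = np.asarray(d, dtype=float)
        if np.any(d_arr <= 0):
            raise ValueError("trans density is undefined at d <= 0 "
                             "(zero distances are excluded from the model)")
        raw = 2.0 * np.clip(self._n - d_arr[..., None], 0.0, None).sum(axis=-1)
        out = raw / self._pairs_total
        return out if out.ndim else float(out)

    def density_log(self, lx):
        """Density per log10 unit at log10-distance ``lx`` (change of variables)."""
        lx_arr = np.asarray(lx, dtype=float)
        d = np.power(10.0, lx_arr)
        out = self.density_linear(d) * d * np.log(10.0)
        return out if np.ndim(lx) else float(out)

    def tail_probability(self, x):
        """P(distance > x) for a random same-chromosome pair.

        Exact under the discrete (integer-bp) model: with ``m`` the smallest
        integer strictly greater than ``x``, the number of ordered pairs at
        distance >= m on a chromosome of length N is ``(N - m)(N - m + 1)``.
        """
        x_arr = np.asarray(x, dtype=float)
        if np.any(x_arr < 0):
            raise ValueError("threshold must be non-negative")
        m = np.floor(x_arr)[..., None] + 1.0
        pairs = np.clip(self._n - m, 0.0, None) * np.clip(self._n - m + 1.0, 0.0, None)
        out = pairs.sum(axis=-1) / self._pairs_total
        return out if out.ndim else float(out)

    def cdf_linear(self, x):
        return 1.0 - self.tail_probability(np.maximum(x, 0.0))

    def cdf_log(self, lx):
        """CDF of log10 distance (P(log10 d <= lx))."""
        lx_arr = np.asarray(lx, dtype=float)
        x = np.power(10.0, np.minimum(lx_arr, self.log_max + 1.0))
        out = np.where(lx_arr < 0, 0.0, 1.0 - self.tail_probability(x))
        return out if out.ndim else float(out)

    @functools.cached_property
    def log_mode(self) -> float:
        """log10 distance at which the per-log10-unit density peaks."""
        res = optimize.minimize_scalar(
            lambda lx: -self.density_log(lx),
            bounds=(1.0, self.log_max), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    # ------------------------------------------------------------------ #
    # sampling

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` random same-chromosome pair distances.

        Returns ``(chrom_index, distance)`` arrays.  A chromosome is chosen
        with probability ``N_i**2 / sum N_j**2``, then two independent uniform
        integer positions are drawn on it; zero differences are redrawn.
        """
        if n < 0:
            raise ValueError("n must be non-negative")
        idx = rng.choice(len(self._n), size=n, p=self.chromosome_weights)
        lengths = self._n[idx].astype(np.int64)
        d = np.zeros(n, dtype=np.int64)
        todo = np.ones(n, dtype=bool)
        while todo.any():
            k = int(todo.sum())
            p1 = rng.integers(1, lengths[todo] + 1, size=k)
            p2 = rng.integers(1, lengths[todo] + 1, size=k)
            d[todo] = np.abs(p1 - p2)
            todo = d == 0
        return idx, d


def sample_trans(n: int, model: TransModel, seed: int | np.random.Generator) -> np.ndarray:
    """Convenience wrapper: ``n`` trans distances in bp at a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return model.sample(n, rng)[1]
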