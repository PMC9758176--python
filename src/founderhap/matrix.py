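"""Unphased diploid genotype matrix keyed by genomic coordinates.

The container used by the IBD streak detector and the haplotype classifier:
samples x sites, with genotypes coded 0 (hom-ref), 1 (het), 2 (hom-alt) and
-1 for missing calls. Sites are strictly sorted by (chromosome, position);
chromosome blocks are contiguous and positions strictly increase within each
block, matching VCF ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    samples: list[str]
    chrom: np.ndarray  # per-site chromosome name
    pos: np.ndarray  # per-site 1-based position
    ref: np.ndarray  # per-site reference base
    alt: np.ndarray  # per-site alternate base
    codes: np.ndarray  # (n_samples, n_sites) int8, -1 = missing
    n_skipped: int = field(default=0, compare=False)  # records dropped on read

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n_sites = self.pos.size
        if not (self.chrom.size == self.ref.size == self.alt.size == n_sites):
            raise ValueError("site annotation arrays must have equal length")
        if self.codes.shape != (len(self.samples), n_sites):
            raise ValueError(
                f"genotype array shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {n_sites} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i in range(self.pos.size):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} split into multiple blocks")
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise ValueError(
                    f"sites not strictly sorted at {c}:{self.pos[i]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ValueError(f"unknown sample {sample!r}") from None

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chromosome: str) -> slice:
        """Index slice covering one chromosome's contiguous site block."""
        idx = np.flatnonzero(self.chrom == chromosome)
        if idx.size == 0:
            raise ValueError(f"chromosome {chromosome!r} not present")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def genotypes_at(self, sample: str, positions, chromosome: str | None = None):
        """Diploid base-pair strings at given positions (for classification).

        Returns ``{position: "GT" | None}``; ``None`` marks a missing call.
        """
        i = self.sample_index(sample)
        sel = np.ones(self.n_sites, dtype=bool)
        if chromosome is not None:
            sel = self.chrom == chromosome
        out: dict[int, str | None] = {}
        for p in positions:
            hits = np.flatnonzero(sel & (self.pos == p))
            if hits.size == 0:
                continue
            j = int(hits[0])
            code = int(self.codes[i, j])
            if code == MISSING:
                out[p] = None
            else:
                r, a = self.ref[j], self.alt[j]
                out[p] = {0: r + r, 1: r + a, 2: a + a}[code]
        return out
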