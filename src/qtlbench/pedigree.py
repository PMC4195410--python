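"""Half-sib pedigree construction and gene dropping with Haldane meiosis.

The breeding design mimics a dairy nucleus: discrete generations, each with
``n_males`` sires and ``n_females`` dams, every sire randomly mated to
``n_females / n_males`` dams.  Each dam leaves one female offspring except
one dam per sire family (the "dam of a male"), which leaves a male and a
female — keeping population sizes constant across generations.

Founder genotypes pair up the constructed gametes at random; descendant
gametes are produced by meiosis with crossovers sampled under Haldane's
mapping function (Poisson crossover counts, uniform positions, no
interference) at a configurable 1 cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .founder_genome import GameteMatrix, GenomeLayout

__all__ = [
    "Pedigree",
    "GenotypeStore",
    "build_pedigree",
    "haldane_recomb_fraction",
    "meiosis",
    "drop_genotypes",
]

MALE, FEMALE = "M", "F"


@dataclass
class Pedigree:
    """Columnar pedigree over non-overlapping generations.

    ``sire`` and ``dam`` hold row indices into the pedigree itself, -1 for
    founders.  ``ids`` are 1-based integer animal identifiers in birth order.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray  # "M"/"F"
    generation: np.ndarray

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def n_generations(self) -> int:
        return int(self.generation.max())

    def rows(self, generation: int | None = None, sex: str | None = None) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        if generation is not None:
            mask &= self.generation == generation
        if sex is not None:
            mask &= self.sex == sex
        return np.flatnonzero(mask)

    def to_frame(self) -> pd.DataFrame:
        sire_id = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], 0)
        dam_id = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], 0)
        return pd.DataFrame({
            "id": self.ids, "sire": sire_id, "dam": dam_id,
            "sex": self.sex, "generation": self.generation,
        })


@dataclass
class GenotypeStore:
    """Phased genotypes for every pedigree member.

    ``haplotypes`` has shape (n_individuals, 2, n_snps) with entries 0/1;
    axis 1 orders the paternal then maternal gamete (arbitrary for founders).
    """

    haplotypes: np.ndarray
    layout: GenomeLayout

    def dosage(self, snp_indices: np.ndarray | None = None,
               rows: np.ndarray | None = None) -> np.ndarray:
        """Count of allele 1 per individual (0/1/2) at the requested SNPs."""
        h = self.haplotypes
        if rows is not None:
            h = h[rows]
        if snp_indices is not None:
            h = h[:, :, snp_indices]
        return h.sum(axis=1, dtype=np.int16)


def build_pedigree(rng: np.random.Generator, n_generations: int = 4,
                   n_males: int = 20, n_females: int = 1000) -> Pedigree:
    """Create the discrete-generation half-sib pedigree.

    Every generation has exactly ``n_males`` males and ``n_females`` females.
    Each sire of generation g-1 is mated to ``n_females // n_males`` distinct
    dams (sampled without replacement, so each dam has one mate).  One dam
    per sire family, chosen uniformly, bears two offspring (a male and a
    female); the others bear one female.
    """
    if n_females % n_males != 0:
        raise ValueError("n_females must be a multiple of n_males")
    dams_per_sire = n_females // n_males
    size = (n_males + n_females) * (n_generations + 1)
    ids = np.arange(1, size + 1)
    sire = np.full(size, -1, dtype=np.int64)
    dam = np.full(size, -1, dtype=np.int64)
    sex = np.empty(size, dtype="U1")
    gen = np.empty(size, dtype=np.int64)

    row = 0
    prev_males: np.ndarray = np.array([], dtype=np.int64)
    prev_females: np.ndarray = np.array([], dtype=np.int64)
    for g in range(n_generations + 1):
        males_this = []
        females_this = []
        if g == 0:
            for _ in range(n_males):
                sex[row], gen[row] = MALE, g
                males_this.append(row); row += 1
            for _ in range(n_females):
                sex[row], gen[row] = FEMALE, g
                females_this.append(row); row += 1
        else:
            dam_order = rng.permutation(prev_females)
            for s_i, s_row in enumerate(prev_males):
                fam_dams = dam_order[s_i * dams_per_sire:(s_i + 1) * dams_per_sire]
                male_dam = fam_dams[rng.integers(len(fam_dams))]
                for d_row in fam_dams:
                    sire[row], dam[row] = s_row, d_row
                    sex[row], gen[row] = FEMALE, g
                    females_this.append(row); row += 1
                    if d_row == male_dam:
                        sire[row], dam[row] = s_row, d_row
                        sex[row], gen[row] = MALE, g
                        males_this.append(row); row += 1
        prev_males = np.array(males_this)
        prev_females = np.array(females_this)
    return Pedigree(ids=ids, sire=sire, dam=dam, sex=sex, generation=gen)


def haldane_recomb_fraction(distance_morgans: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction under Haldane's mapping function.

    c = (1 - exp(-2 d)) / 2 for map distance d in Morgans; no interference.
    """
    d = np.asarray(distance_morgans, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(out) if out.ndim == 0 else out


def meiosis(parent_haplotypes: np.ndarray, layout: GenomeLayout,
            rng: np.random.Generator, cm_per_mb: float = 1.0) -> np.ndarray:
    """Produce one gamete from a parent's pair of haplotypes.

    Per chromosome, the crossover count is Poisson with mean equal to the
    chromosome map length (Morgans) and crossover positions are uniform —
    Haldane's model.  The starting haplotype is chosen with probability 1/2.
    """
    n_snps = layout.n_snps
    gamete = np.empty(n_snps, dtype=parent_haplotypes.dtype)
    morgans = layout.chrom_length_mb * cm_per_mb / 100.0
    per_chrom = layout.snps_per_chrom
    pos = layout.pos_mb[:per_chrom]
    for c in range(layout.n_chromosomes):
        sl = slice(c * per_chrom, (c + 1) * per_chrom)
        n_xo = rng.poisson(morgans)
        phase0 = rng.integers(2)
        if n_xo == 0:
            gamete[sl] = parent_haplotypes[phase0, sl]
            continue
        xo_pos = np.sort(rng.uniform(0.0, layout.chrom_length_mb, size=n_xo))
        # phase at each SNP = start phase + number of crossovers to its left
        n_left = np.searchsorted(xo_pos, pos)
        phase = (phase0 + n_left) % 2
        seg = parent_haplotypes[:, sl]
        gamete[sl] = np.where(phase == 0, seg[0], seg[1])
    return gamete


def drop_genotypes(pedigree: Pedigree, founders: GameteMatrix,
                   rng: np.random.Generator, cm_per_mb: float = 1.0) -> GenotypeStore:
    """Assign genotypes to the whole pedigree.

    Founder gametes are shuffled and combined two-by-two into the generation-0
    genotypes (so 2N gametes are needed for N founders); every descendant
    receives one meiotic gamete from each parent, sire first.
    """
    layout = founders.layout
    founder_rows = np.flatnonzero(pedigree.generation == 0)
    if founders.n_gametes != 2 * founder_rows.size:
        raise ValueError(
            f"need {2 * founder_rows.size} founder gametes, have {founders.n_gametes}")
    haps = np.empty((pedigree.n, 2, layout.n_snps), dtype=np.int8)
    perm = rng.permutation(founders.n_gametes)
    haps[founder_rows] = founders.alleles[perm].reshape(founder_rows.size, 2, -1)

    order = np.argsort(pedigree.generation, kind="stable")
    for row in order:
        s, d = pedigree.sire[row], pedigree.dam[row]
        if s < 0:
            continue
        if pedigree.generation[s] >= pedigree.generation[row]:
            raise ValueError("parent born after offspring")
        haps[row, 0] = meiosis(haps[s], layout, rng, cm_per_mb)
        haps[row, 1] = meiosis(haps[d], layout, rng, cm_per_mb)
    return GenotypeStore(haplotypes=haps, layout=layout)
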