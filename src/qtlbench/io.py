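"""File formats: participant exports, truth files, submissions, run state.

Participant-facing genotypes go out as PLINK PED/MAP over the released map
(positions in base pairs = Mb x 10^6, 1-based; alleles coded A/B), or as a
tab-separated dosage matrix.  Generation-0 females are excluded from
genotype exports, matching the workshop release.  Mapping submissions are
TSVs with columns ``trait, chromosome, position_mb``; DGV submissions have
``id, trait, dgv``.  A compressed npz + JSON pair persists a full run so the
screening/scoring commands can reload it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .founder_genome import GameteMatrix, GenomeLayout, LDProfile, hide_even_snps
from .pedigree import GenotypeStore, Pedigree
from .pipeline import SimulationResult
from .traits import QTLSet, TRAITS, TraitConfig

__all__ = [
    "genotyped_rows", "write_map", "write_ped", "write_dosage_matrix",
    "write_pedigree", "write_phenotypes", "write_qtl_truth", "write_tbv",
    "read_mapping_submission", "read_dgv", "write_dgv",
    "save_state", "load_state",
]

ALLELE_CODES = ("B", "A")  # allele2 -> "B", allele1 -> "A"


def genotyped_rows(result: SimulationResult) -> np.ndarray:
    """Pedigree rows whose genotypes are released (all but G0 females)."""
    ped = result.pedigree
    mask = ~((ped.generation == 0) & (ped.sex == "F"))
    return np.flatnonzero(mask)


def write_map(path: str | Path, result: SimulationResult) -> None:
    """PLINK MAP for the released markers (bp = Mb x 1e6)."""
    rel = result.released
    bp = np.round(rel.pos_mb * 1e6).astype(np.int64)
    df = pd.DataFrame({"chrom": rel.chromosome, "snp": rel.snp_ids,
                       "cm": 0.0, "bp": bp})
    df.to_csv(path, sep="\t", header=False, index=False)


def write_ped(path: str | Path, result: SimulationResult) -> None:
    """PLINK PED over the released map, excluding generation-0 females."""
    rows = genotyped_rows(result)
    ped = result.pedigree
    rel_idx = result.released.released_indices
    haps = result.genotypes.haplotypes[np.ix_(rows, [0, 1], rel_idx)]
    sire = np.where(ped.sire[rows] >= 0, ped.ids[np.maximum(ped.sire[rows], 0)], 0)
    dam = np.where(ped.dam[rows] >= 0, ped.ids[np.maximum(ped.dam[rows], 0)], 0)
    sexcode = np.where(ped.sex[rows] == "M", 1, 2)
    codes = np.array(ALLELE_CODES)
    with open(path, "w") as fh:
        for i, row in enumerate(rows):
            g = codes[haps[i]]  # (2, n_released)
            geno = " ".join(a + " " + b for a, b in zip(g[0], g[1]))
            fh.write(f"FAM1 {ped.ids[row]} {sire[i]} {dam[i]} "
                     f"{sexcode[i]} -9 {geno}\n")


def write_dosage_matrix(path: str | Path, result: SimulationResult) -> None:
    """Released-marker allele-1 dosages, one genotyped individual per row."""
    rows = genotyped_rows(result)
    dos = result.released_dosages(rows)
    df = pd.DataFrame(dos, columns=result.released.snp_ids)
    df.insert(0, "id", result.pedigree.ids[rows])
    df.to_csv(path, sep="\t", index=False)


def write_pedigree(path: str | Path, result: SimulationResult) -> None:
    result.pedigree.to_frame().to_csv(path, sep="\t", index=False)


def write_phenotypes(path: str | Path, result: SimulationResult) -> None:
    result.phenotype_frame().to_csv(path, sep="\t", index=False,
                                    float_format="%.6f")


def write_qtl_truth(path: str | Path, result: SimulationResult) -> None:
    result.qtlset.to_frame().to_csv(path, sep="\t", index=False,
                                    float_format="%.8g")


def write_tbv(path: str | Path, result: SimulationResult) -> None:
    result.tbv_frame().to_csv(path, sep="\t", index=False,
                              float_format="%.6f")


def read_mapping_submission(path: str | Path) -> pd.DataFrame:
    """Read a QTL-mapping submission (trait, chromosome, position_mb)."""
    df = pd.read_csv(path, sep="\t")
    required = {"trait", "chromosome", "position_mb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing submission columns {sorted(missing)}")
    bad = ~df["trait"].isin(TRAITS)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: unknown trait on line(s) {lines}")
    if (df["position_mb"] < 0).any():
        raise ValueError(f"{path}: negative positions")
    return df


def write_dgv(path: str | Path, ids: np.ndarray, trait: str,
              dgv: np.ndarray) -> None:
    pd.DataFrame({"id": ids, "trait": trait, "dgv": dgv}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_dgv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"id", "trait", "dgv"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DGV columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# run-state persistence


def _config_to_dict(cfg: RunConfig) -> dict:
    if cfg.profile.kind == "custom":
        raise ValueError("custom LD profiles cannot be persisted")
    return {
        "layout": dataclasses.asdict(cfg.layout),
        "profile": {k: v for k, v in dataclasses.asdict(cfg.profile).items()
                    if k != "custom"},
        "traits": dataclasses.asdict(cfg.traits),
        "run": {k: getattr(cfg, k) for k in
                ("n_males", "n_females", "n_generations", "cm_per_mb",
                 "alpha_overall", "seed")},
    }


def _config_from_dict(d: dict) -> RunConfig:
    traits = d["traits"].copy()
    traits["h2"] = tuple(traits["h2"])
    traits["target_rg"] = tuple(traits["target_rg"])
    traits["omega_class_counts"] = tuple(traits["omega_class_counts"])
    return RunConfig(layout=GenomeLayout(**d["layout"]),
                     profile=LDProfile(**d["profile"]),
                     traits=TraitConfig(**traits), **d["run"])


def save_state(directory: str | Path, result: SimulationResult) -> None:
    """Persist a run (binary npz + config JSON) for later CLI steps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "config.json").write_text(
        json.dumps(_config_to_dict(result.config), indent=1))
    np.savez_compressed(
        directory / "state.npz",
        haplotypes=result.genotypes.haplotypes,
        founder_alleles=result.gametes.alleles,
        prior_freqs=result.gametes.prior_freqs,
        realized_freqs=result.gametes.realized_freqs,
        ped_ids=result.pedigree.ids, ped_sire=result.pedigree.sire,
        ped_dam=result.pedigree.dam, ped_sex=result.pedigree.sex,
        ped_gen=result.pedigree.generation,
        qtl_positions=result.qtlset.positions,
        qtl_alpha_sdu=result.qtlset.alpha_sdu, qtl_omega=result.qtlset.omega,
        qtl_class=result.qtlset.omega_class, qtl_alpha_t=result.qtlset.alpha_t,
        qtl_p=result.qtlset.p,
        tbv=result.tbv, yd=result.yd, residuals=result.residuals,
        phenotyped_rows=result.phenotyped_rows,
        candidate_rows=result.candidate_rows)


def load_state(directory: str | Path) -> SimulationResult:
    directory = Path(directory)
    cfg = _config_from_dict(json.loads((directory / "config.json").read_text()))
    z = np.load(directory / "state.npz")
    layout = cfg.layout
    gametes = GameteMatrix(alleles=z["founder_alleles"],
                           prior_freqs=z["prior_freqs"],
                           realized_freqs=z["realized_freqs"], layout=layout)
    pedigree = Pedigree(ids=z["ped_ids"], sire=z["ped_sire"],
                        dam=z["ped_dam"], sex=z["ped_sex"],
                        generation=z["ped_gen"])
    genotypes = GenotypeStore(haplotypes=z["haplotypes"], layout=layout)
    positions = z["qtl_positions"]
    qtlset = QTLSet(positions=positions,
                    chromosome=layout.chrom_of_snp[positions],
                    pos_mb=layout.pos_mb[positions],
                    alpha_sdu=z["qtl_alpha_sdu"], omega=z["qtl_omega"],
                    omega_class=z["qtl_class"], alpha_t=z["qtl_alpha_t"],
                    p=z["qtl_p"], config=cfg.traits)
    return SimulationResult(config=cfg, gametes=gametes,
                            released=hide_even_snps(layout),
                            pedigree=pedigree, genotypes=genotypes,
                            qtlset=qtlset, tbv=z["tbv"],
                            phenotyped_rows=z["phenotyped_rows"],
                            candidate_rows=z["candidate_rows"],
                            yd=z["yd"], residuals=z["residuals"])
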