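"""End-to-end simulation pipeline and the GBLUP reference run.

``run_simulation`` chains founder-genome construction, pedigree expansion,
gene dropping, QTL-architecture tuning and phenotype synthesis into one
reproducible dataset object that the screening, scoring and prediction
steps consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .detectability import DetectabilityReport, bonferroni_threshold, flag_detectable
from .evaluation import PredictionScore, score_prediction
from .founder_genome import GameteMatrix, ReleasedMap, build_founder_gametes, hide_even_snps
from .pedigree import GenotypeStore, Pedigree, build_pedigree, drop_genotypes
from .predictors import compute_grm, gblup_predict
from .traits import (QTLSet, TRAITS, assign_and_tune_omega, compute_tbv,
                     sample_qtl_positions, sample_standardized_effects,
                     simulate_phenotypes, trait_effects)

__all__ = ["SimulationResult", "run_simulation", "run_detectability",
           "gblup_reference", "score_gblup_reference"]


@dataclass
class SimulationResult:
    """One simulated dataset plus the truth needed to evaluate analyses."""

    config: RunConfig
    gametes: GameteMatrix
    released: ReleasedMap
    pedigree: Pedigree
    genotypes: GenotypeStore
    qtlset: QTLSet
    tbv: np.ndarray              # (n_individuals, 3), centered on phenotyped
    phenotyped_rows: np.ndarray  # pedigree rows with phenotypes
    candidate_rows: np.ndarray   # last-generation rows (prediction targets)
    yd: np.ndarray               # (n_phenotyped, 3)
    residuals: np.ndarray

    @property
    def qtl_dosages_phenotyped(self) -> np.ndarray:
        return self.genotypes.dosage(self.qtlset.positions, self.phenotyped_rows)

    def released_dosages(self, rows: np.ndarray) -> np.ndarray:
        return self.genotypes.dosage(self.released.released_indices, rows)

    def phenotype_frame(self) -> pd.DataFrame:
        ids = self.pedigree.ids[self.phenotyped_rows]
        cols = {"id": ids}
        for t, name in enumerate(TRAITS):
            cols[f"yd_{name.lower()}"] = self.yd[:, t]
        return pd.DataFrame(cols)

    def tbv_frame(self, rows: np.ndarray | None = None) -> pd.DataFrame:
        rows = np.arange(self.pedigree.n) if rows is None else rows
        cols = {"id": self.pedigree.ids[rows]}
        for t, name in enumerate(TRAITS):
            cols[f"tbv_{name.lower()}"] = self.tbv[rows, t]
        return pd.DataFrame(cols)


def run_simulation(config: RunConfig) -> SimulationResult:
    """Simulate one dataset under a configuration.

    Stages draw from independent seeded substreams.  QTL allele frequencies,
    effect standardization, omega tuning and TBV centering all use the
    phenotyped generations (females of every generation but the last), the
    sample on which genetic parameters are defined.
    """
    layout, profile, tcfg = config.layout, config.profile, config.traits

    gametes = build_founder_gametes(layout, profile, config.rng("genome"),
                                    n_gametes=config.n_founder_gametes)
    released = hide_even_snps(layout)

    rng_ped = config.rng("pedigree")
    pedigree = build_pedigree(rng_ped, n_generations=config.n_generations,
                              n_males=config.n_males, n_females=config.n_females)
    genotypes = drop_genotypes(pedigree, gametes, rng_ped, config.cm_per_mb)

    phen_rows = np.flatnonzero(
        np.isin(pedigree.generation, config.phenotyped_generations)
        & (pedigree.sex == "F"))
    cand_rows = pedigree.rows(generation=config.candidate_generation)

    rng_qtl = config.rng("qtl")
    positions = sample_qtl_positions(released.hidden_indices, tcfg.n_qtl, rng_qtl)
    dos_phen = genotypes.dosage(positions, phen_rows)
    p = dos_phen.mean(axis=0) / 2.0
    alpha_sdu = sample_standardized_effects(p, tcfg, rng_qtl)
    omega, labels = assign_and_tune_omega(alpha_sdu, dos_phen, tcfg, rng_qtl)
    alpha_t = trait_effects(alpha_sdu, omega, tcfg)
    qtlset = QTLSet(positions=positions,
                    chromosome=layout.chrom_of_snp[positions],
                    pos_mb=layout.pos_mb[positions],
                    alpha_sdu=alpha_sdu, omega=omega, omega_class=labels,
                    alpha_t=alpha_t, p=p, config=tcfg)

    tbv = compute_tbv(genotypes.dosage(positions), alpha_t, center_rows=phen_rows)
    phen = simulate_phenotypes(tbv[phen_rows], tcfg, config.rng("residuals"))

    return SimulationResult(config=config, gametes=gametes, released=released,
                            pedigree=pedigree, genotypes=genotypes,
                            qtlset=qtlset, tbv=tbv, phenotyped_rows=phen_rows,
                            candidate_rows=cand_rows, yd=phen["yd"],
                            residuals=phen["residual"])


def run_detectability(result: SimulationResult) -> DetectabilityReport:
    """Organizers' screen: joint regression of YD on all true QTL dosages.

    The Bonferroni correction counts the *released* markers — the tests an
    analyst would run — not the 50 true QTLs.
    """
    thr = bonferroni_threshold(result.config.alpha_overall,
                               result.released.n_released)
    return flag_detectable(result.yd, result.qtl_dosages_phenotyped,
                           result.qtlset, thr)


def gblup_reference(result: SimulationResult, trait: int) -> np.ndarray:
    """GBLUP DGV for the candidate generation from released-marker dosages.

    The GRM covers training females and candidates jointly, centered at
    training-set allele frequencies; the variance ratio comes from the
    trait's simulated heritability.
    """
    rows = np.concatenate([result.phenotyped_rows, result.candidate_rows])
    dos = result.released_dosages(rows)
    n_train = result.phenotyped_rows.size
    freqs = dos[:n_train].mean(axis=0) / 2.0
    grm = compute_grm(dos, freqs=freqs)
    train_idx = np.arange(n_train)
    cand_idx = np.arange(n_train, rows.size)
    return gblup_predict(result.yd[:, trait], grm, train_idx, cand_idx,
                         h2=result.config.traits.h2[trait])


def score_gblup_reference(result: SimulationResult, trait: int) -> PredictionScore:
    """Accuracy and bias of the GBLUP reference on the candidates."""
    dgv = gblup_reference(result, trait)
    tbv = result.tbv[result.candidate_rows, trait]
    return score_prediction(dgv, tbv)
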