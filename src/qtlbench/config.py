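"""Run configuration, scale profiles and seeded random substreams.

All randomness flows from one master seed through named substreams, one per
pipeline stage (founder genome, pedigree and meiosis, QTL architecture,
phenotype residuals).  Substream k is ``SeedSequence(master, spawn_key=(k,))``
with a fixed name-to-k mapping, so changing one stage's stream leaves every
other stage's draws untouched and partial re-runs are reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .founder_genome import GenomeLayout, LDProfile
from .traits import TraitConfig, scaled_class_counts

__all__ = ["RunConfig", "substream_rng", "STREAMS", "parse_config_file"]

#: fixed substream indices; never renumber, or seeded runs change meaning
STREAMS = {"genome": 0, "pedigree": 1, "qtl": 2, "residuals": 3}


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named pipeline stage."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STREAMS[name],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class RunConfig:
    """Everything that defines one simulated dataset.

    The ``full`` profile is the default study scale: 5 x 100 Mb chromosomes,
    1,020 founders (2,040 gametes), four descendant generations of 20 males
    and 1,000 females, 50 QTLs, phenotypes on the first three descendant
    generations' females, genomic prediction on the last generation.  The
    ``mini`` profile is a structurally identical reduction (1 chromosome,
    400 SNPs, 100 founders, 3 generations, 10 QTLs) that runs a complete
    pipeline in seconds for tests and examples.
    """

    layout: GenomeLayout = field(default_factory=GenomeLayout)
    profile: LDProfile = field(default_factory=LDProfile)
    traits: TraitConfig = field(default_factory=TraitConfig)
    n_males: int = 20
    n_females: int = 1000
    n_generations: int = 4
    cm_per_mb: float = 1.0
    alpha_overall: float = 0.05
    seed: int = 0

    @property
    def n_founders(self) -> int:
        return self.n_males + self.n_females

    @property
    def n_founder_gametes(self) -> int:
        return 2 * self.n_founders

    @property
    def phenotyped_generations(self) -> tuple[int, ...]:
        """Generations whose females carry phenotypes (all but the last)."""
        return tuple(range(1, self.n_generations))

    @property
    def candidate_generation(self) -> int:
        return self.n_generations

    def rng(self, name: str) -> np.random.Generator:
        return substream_rng(self.seed, name)

    @classmethod
    def full(cls, seed: int = 0) -> "RunConfig":
        return cls(seed=seed)

    @classmethod
    def mini(cls, seed: int = 0) -> "RunConfig":
        layout = GenomeLayout(n_chromosomes=1, chrom_length_mb=10.0,
                              snps_per_chrom=400)
        traits = TraitConfig(n_qtl=10, omega_class_counts=scaled_class_counts(10),
                             n_restarts=4, max_sweeps=30)
        return cls(layout=layout, traits=traits, n_males=4, n_females=96,
                   n_generations=3, seed=seed)


_PROFILES = {"full": RunConfig.full, "mini": RunConfig.mini}


def parse_config_file(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    """Build a RunConfig from a flat ``key = value`` text file.

    Recognized keys: ``profile`` (full|mini, applied first), the layout
    fields (n_chromosomes, chrom_length_mb, snps_per_chrom, ld_window), LD
    fields (ld_profile, sigma_r), pedigree fields (n_males, n_females,
    n_generations, cm_per_mb), trait fields (n_qtl, rg_tol), and ``seed``.
    Unknown keys raise with the offending name.
    """
    text = Path(path).read_text()
    kv: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v

    cfg = base
    if "profile" in kv:
        name = kv.pop("profile")
        if name not in _PROFILES:
            raise ValueError(f"unknown profile {name!r}; choose full or mini")
        cfg = _PROFILES[name]()
    if cfg is None:
        cfg = RunConfig.full()

    layout_keys = {"n_chromosomes": int, "chrom_length_mb": float,
                   "snps_per_chrom": int, "ld_window": int}
    ld_keys = {"ld_profile": str, "sigma_r": float}
    run_keys = {"n_males": int, "n_females": int, "n_generations": int,
                "cm_per_mb": float, "alpha_overall": float, "seed": int}
    trait_keys = {"n_qtl": int, "rg_tol": float}

    layout_updates, ld_updates, run_updates, trait_updates = {}, {}, {}, {}
    for k, v in kv.items():
        if k in layout_keys:
            layout_updates[k] = layout_keys[k](v)
        elif k == "ld_profile":
            ld_updates["kind"] = v
        elif k == "sigma_r":
            ld_updates["sigma_r"] = float(v)
        elif k in run_keys:
            run_updates[k] = run_keys[k](v)
        elif k in trait_keys:
            trait_updates[k] = trait_keys[k](v)
        else:
            raise ValueError(f"unknown config key {k!r}")
    if layout_updates:
        cfg = replace(cfg, layout=replace(cfg.layout, **layout_updates))
    if ld_updates:
        cfg = replace(cfg, profile=replace(cfg.profile, **ld_updates))
    if trait_updates:
        if "n_qtl" in trait_updates:
            trait_updates.setdefault(
                "omega_class_counts",
                scaled_class_counts(trait_updates["n_qtl"]))
        cfg = replace(cfg, traits=replace(cfg.traits, **trait_updates))
    if run_updates:
        cfg = replace(cfg, **run_updates)
    return cfg
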