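"""Study-like synthetic MLST datasets.

Generates a dataset emulating the sampling design of the black-locust
rhizobium collection: 286 haploid strains in three symbiotic-gene clades of
82/97/87 members (plus 20 admixed strains), genotyped at five symbiotic
loci (nodA 535, nodC 798, nifA 693, nifH 686, nolT 596 bp) and six
housekeeping loci, with a simultaneous three-clade divergence near 204,300
generations before present and a 100-fold demographic expansion of Clade II
near 3,690 generations before present, at a per-site mutation rate of
1e-8 per generation.

Housekeeping loci are simulated with a 10x mutation-rate multiplier to
reproduce the order-of-magnitude diversity contrast between housekeeping
and symbiotic genes; recombination is not simulated.  Country labels follow
the study's composition (Clades I/II mostly Chinese; Clade III mixing
German, North American and Chinese strains); species labels are cosmetic.

The returned truth record carries every generating parameter so parameter
recovery can be scored without re-reading the configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .coalescent_sim import Deme, DemographicScenario, Event, Locus, simulate_dataset
from .mlst_io import MLSTDataset, attach_metadata, write_loci_fasta, write_metadata
from .scenarios import HOUSEKEEPING_LOCI, SYMBIOTIC_LOCI

__all__ = ["StudyEmulationConfig", "generate_study_like_dataset", "write_study_dataset"]

SPECIES = ("MA", "MH", "ML", "MM", "MR", "MQ", "MS", "MC")


@dataclass
class StudyEmulationConfig:
    """Defaults reproduce the study's sampling design and point estimates."""

    clade_sizes: tuple[int, int, int] = (82, 97, 87)
    n_admixed: int = 20
    divergence_time: float = 204_300.0
    expansion_time: float = 3_690.0
    expansion_fold: float = 100.0
    mu: float = 1e-8
    deme_size: float = 1e5          # present-day gene copies per clade
    ancestral_size: float = 1e5
    housekeeping_theta_multiplier: float = 10.0
    symbiotic_loci: tuple = tuple(SYMBIOTIC_LOCI)
    housekeeping_loci: tuple = tuple(HOUSEKEEPING_LOCI)
    include_housekeeping: bool = True
    n_china_sites: int = 8
    seed: int | None = None

    def validate(self) -> None:
        if any(s <= 0 for s in self.clade_sizes) or self.n_admixed < 0:
            raise ValueError("sample sizes must be positive")
        if not 0 < self.expansion_time < self.divergence_time:
            raise ValueError("expansion must predate divergence (backwards)")
        if self.expansion_fold <= 1:
            raise ValueError("expansion_fold must exceed 1")
        if min(self.mu, self.deme_size, self.ancestral_size) <= 0:
            raise ValueError("rates and sizes must be positive")


def _scenario(cfg: StudyEmulationConfig, samples: dict[str, int],
              mu_mult: float, loci_pairs) -> DemographicScenario:
    demes = [Deme("CI", cfg.deme_size), Deme("CII", cfg.deme_size),
             Deme("CIII", cfg.deme_size)]
    events = [
        # Clade II was 100-fold smaller before its expansion
        Event(time=cfg.expansion_time, kind="size", deme="CII",
              value=cfg.deme_size / cfg.expansion_fold),
        Event(time=cfg.divergence_time, kind="merge", deme="CI", dest="CIII"),
        Event(time=cfg.divergence_time, kind="merge", deme="CII", dest="CIII"),
        Event(time=cfg.divergence_time, kind="size", deme="CIII",
              value=cfg.ancestral_size),
    ]
    loci = [Locus(nm, L, cfg.mu * mu_mult) for nm, L in loci_pairs]
    return DemographicScenario(demes, samples, loci, events=events,
                               label="study_emulation")


def _metadata(cfg: StudyEmulationConfig, strain_clades: list[tuple[str, str]],
              rng: np.random.Generator):
    """Country/site assignment mimicking the study's composition."""
    import pandas as pd
    rows = []
    ciii_countries = ["Germany"] * 48 + ["NorthAmerica"] * 9 + ["China"] * 30
    ci_countries = ["NorthAmerica"] * 2  # the two North American CI strains
    i_ciii = i_ci = 0
    china_sites = [f"CN{i + 1:02d}" for i in range(cfg.n_china_sites)]
    for sid, clade in strain_clades:
        if clade == "CIII" and i_ciii < len(ciii_countries):
            country = ciii_countries[i_ciii]
            i_ciii += 1
        elif clade == "CI" and i_ci < len(ci_countries):
            country = ci_countries[i_ci]
            i_ci += 1
        else:
            country = "China"
        if country == "China":
            site = china_sites[int(rng.integers(len(china_sites)))]
        elif country == "Germany":
            site = "Freiburg"
        else:
            site = "Berkeley"
        species = SPECIES[int(rng.integers(len(SPECIES)))]
        rows.append({"strain": sid, "site": site, "country": country,
                     "species": species, "clade": clade})
    return pd.DataFrame(rows)


def generate_study_like_dataset(cfg: StudyEmulationConfig | None = None
                                ) -> tuple[MLSTDataset, dict]:
    """Simulate the full study-like dataset; returns (dataset, truth record).

    Admixed strains are extra samples drawn from the three demes in
    proportion to clade size and labelled ``admixed`` in the metadata (their
    true deme is recorded in the truth record).
    """
    cfg = cfg or StudyEmulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    extra = rng.multinomial(cfg.n_admixed,
                            np.asarray(cfg.clade_sizes) / sum(cfg.clade_sizes))
    samples = {"CI": cfg.clade_sizes[0] + int(extra[0]),
               "CII": cfg.clade_sizes[1] + int(extra[1]),
               "CIII": cfg.clade_sizes[2] + int(extra[2])}
    sym = _scenario(cfg, samples, 1.0, cfg.symbiotic_loci)
    seeds = rng.integers(2 ** 31, size=4)
    sim_sym = simulate_dataset(sym, seed=int(seeds[0]))
    sims = [sim_sym]
    if cfg.include_housekeeping:
        hk = _scenario(cfg, samples, cfg.housekeeping_theta_multiplier,
                       cfg.housekeeping_loci)
        sims.append(simulate_dataset(hk, seed=int(seeds[1])))

    # strain ids grouped by deme; the last `extra[d]` of each deme are the
    # admixed strains
    ids, clade_labels, true_deme = [], [], []
    counter = 1
    for d, (deme, total) in enumerate(samples.items()):
        n_core = cfg.clade_sizes[d]
        for k in range(total):
            sid = f"RP{counter:04d}"
            counter += 1
            ids.append(sid)
            true_deme.append(deme)
            clade_labels.append(deme if k < n_core else "admixed")

    render_rng = np.random.default_rng(int(seeds[2]))
    dsets = [s.render_sequences(rng=render_rng, strain_ids=ids) for s in sims]
    loci = [l for d in dsets for l in d.loci]
    meta = _metadata(cfg, list(zip(ids, clade_labels)),
                     np.random.default_rng(int(seeds[3])))
    ds = MLSTDataset(loci)
    ds = attach_metadata(ds, meta)
    truth = {
        "config": asdict(cfg),
        "samples": samples,
        "true_deme": dict(zip(ids, true_deme)),
        "divergence_time": cfg.divergence_time,
        "expansion_time": cfg.expansion_time,
        "expansion_fold": cfg.expansion_fold,
        "mu": cfg.mu,
        "deme_size": cfg.deme_size,
        "ancestral_size": cfg.ancestral_size,
    }
    return ds, truth


def write_study_dataset(ds: MLSTDataset, truth: dict, directory) -> None:
    """Emit FASTA per locus + metadata TSV + truth JSON."""
    import os
    os.makedirs(directory, exist_ok=True)
    write_loci_fasta(ds, directory)
    write_metadata(ds, os.path.join(directory, "metadata.tsv"))
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
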