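"""Shipped demographic scenarios for the three-clade model comparison.

Each template maps a parameter dictionary (drawn from the priors) to a
:class:`~rhizodem.coalescent_sim.DemographicScenario` over the clades
CI/CII/CIII of symbiotic-gene haplotypes:

- ``model_09``: sequential divergence — CII splits from CIII at t1, CI
  splits from CIII at t2 > t1 (CIII is the ancestral lineage).
- ``model_10``: simultaneous trifurcation of the three clades at t1.
- ``model_14a``: a ghost (unsampled) deme splits from the ancestral
  population; CII derives from the ghost.
- ``model_14b``: as 14a but the ghost derives from CIII.
- ``model_20``: two-deme split (Chinese vs North American subclades of
  CIII) for divergence-time estimation.

Default priors: divergence times uniform(1e3, 1e6) generations; deme sizes
log-uniform(1e3, 1e6) gene copies; per-site mutation rate log-uniform
(0.5e-8, 2e-8) per generation, shared across loci.  All are overridable.
Sample sizes default to 82/97/87 and loci to the five symbiotic genes.
"""

from __future__ import annotations

from .abc_inference import PriorSpec
from .coalescent_sim import Deme, DemographicScenario, Event, Locus

__all__ = [
    "SYMBIOTIC_LOCI",
    "HOUSEKEEPING_LOCI",
    "DEFAULT_SAMPLES",
    "default_prior",
    "TEMPLATES",
    "model_09",
    "model_10",
    "model_14a",
    "model_14b",
    "model_20",
]

#: the five symbiotic loci (name, aligned length in bp)
SYMBIOTIC_LOCI = [("nodA", 535), ("nodC", 798), ("nifA", 693),
                  ("nifH", 686), ("nolT", 596)]
#: the six housekeeping loci
HOUSEKEEPING_LOCI = [("recA", 475), ("atpD", 468), ("glnII", 658),
                     ("dnaJ", 758), ("rpoA", 684), ("gryB", 713)]

DEFAULT_SAMPLES = {"CI": 82, "CII": 97, "CIII": 87}

CLADES = ("CI", "CII", "CIII")


def _loci(mu: float, loci=None, scale: float = 1.0) -> list[Locus]:
    pairs = loci if loci is not None else SYMBIOTIC_LOCI
    return [Locus(nm, max(2, int(round(L * scale))), mu) for nm, L in pairs]


def default_prior(model: str) -> PriorSpec:
    sizes = {f"N_{c}": ("loguniform", 1e3, 1e6) for c in CLADES}
    common = {**sizes, "N_ANC": ("loguniform", 1e3, 1e6),
              "mu": ("loguniform", 0.5e-8, 2e-8)}
    if model == "model_10":
        return PriorSpec({**common, "t1": ("uniform", 1e3, 1e6)})
    if model == "model_09":
        # t1 < t2 enforced by sorting two independent uniforms
        spec = PriorSpec({**common,
                          "t1": ("uniform", 1e3, 1e6),
                          "t2": ("uniform", 1e3, 1e6)})

        def order(df):
            import numpy as np
            lo = np.minimum(df["t1"], df["t2"])
            hi = np.maximum(df["t1"], df["t2"])
            df["t1"] = lo
            return hi

        spec.derived = {"t2": order}
        return spec
    if model in ("model_14a", "model_14b"):
        spec = PriorSpec({**common,
                          "N_GHOST": ("loguniform", 1e3, 1e6),
                          "t1": ("uniform", 1e3, 1e6),
                          "t2": ("uniform", 1e3, 1e6),
                          "t3": ("uniform", 1e3, 1e6)})

        def order14(df):
            import numpy as np
            ts = np.sort(df[["t1", "t2", "t3"]].to_numpy(), axis=1)
            df["t1"], df["t2"] = ts[:, 0], ts[:, 1]
            return ts[:, 2]

        spec.derived = {"t3": order14}
        return spec
    if model == "model_20":
        return PriorSpec({"N_CN": ("loguniform", 1e3, 1e6),
                          "N_NA": ("loguniform", 1e3, 1e6),
                          "N_ANC": ("loguniform", 1e3, 1e6),
                          "mu": ("loguniform", 0.5e-8, 2e-8),
                          "t1": ("uniform", 1e3, 1e6)})
    raise ValueError(f"unknown model {model!r}")


def _clade_demes(p) -> list[Deme]:
    return [Deme("CI", p["N_CI"]), Deme("CII", p["N_CII"]),
            Deme("CIII", p["N_CIII"])]


def model_10(p, samples=None, loci=None, locus_scale: float = 1.0) -> DemographicScenario:
    """Simultaneous trifurcation at t1."""
    t1 = p["t1"]
    events = [Event(time=t1, kind="merge", deme="CI", dest="CIII"),
              Event(time=t1, kind="merge", deme="CII", dest="CIII"),
              Event(time=t1, kind="size", deme="CIII", value=p["N_ANC"])]
    return DemographicScenario(_clade_demes(p), samples or dict(DEFAULT_SAMPLES),
                               _loci(p["mu"], loci, locus_scale), events=events,
                               label="model_10")


def model_09(p, samples=None, loci=None, locus_scale: float = 1.0) -> DemographicScenario:
    """CII from CIII at t1, CI from CIII at t2 > t1."""
    t1, t2 = p["t1"], p["t2"]
    if not t1 < t2:
        t1, t2 = min(t1, t2), max(t1, t2)
        if t1 == t2:
            t2 = t1 * (1 + 1e-9) + 1e-6
    events = [Event(time=t1, kind="merge", deme="CII", dest="CIII"),
              Event(time=t2, kind="merge", deme="CI", dest="CIII"),
              Event(time=t2, kind="size", deme="CIII", value=p["N_ANC"])]
    return DemographicScenario(_clade_demes(p), samples or dict(DEFAULT_SAMPLES),
                               _loci(p["mu"], loci, locus_scale), events=events,
                               label="model_09")


def _model_14(p, ghost_source: str, label: str, samples=None, loci=None,
              locus_scale: float = 1.0) -> DemographicScenario:
    """CII derives from an unsampled ghost deme.

    With ``ghost_source="ancestral"`` the ghost joins the post-divergence
    ancestral population (backwards: CII->GHOST at t1, CI->CIII at t2,
    GHOST->CIII at t3); with ``ghost_source="CIII"`` the ghost joins CIII
    while CIII is still a distinct lineage (GHOST->CIII at t2, CI->CIII
    at t3)."""
    t1, t2, t3 = sorted((p["t1"], p["t2"], p["t3"]))
    t2 = max(t2, t1 + 1e-9)
    t3 = max(t3, t2 + 1e-9)
    demes = _clade_demes(p) + [Deme("GHOST", p["N_GHOST"])]
    if ghost_source == "ancestral":
        events = [Event(time=t1, kind="merge", deme="CII", dest="GHOST"),
                  Event(time=t2, kind="merge", deme="CI", dest="CIII"),
                  Event(time=t3, kind="merge", deme="GHOST", dest="CIII"),
                  Event(time=t3, kind="size", deme="CIII", value=p["N_ANC"])]
    else:
        events = [Event(time=t1, kind="merge", deme="CII", dest="GHOST"),
                  Event(time=t2, kind="merge", deme="GHOST", dest="CIII"),
                  Event(time=t3, kind="merge", deme="CI", dest="CIII"),
                  Event(time=t3, kind="size", deme="CIII", value=p["N_ANC"])]
    sc = DemographicScenario(demes, samples or dict(DEFAULT_SAMPLES),
                             _loci(p["mu"], loci, locus_scale), events=events,
                             label=label)
    sc.meta = {"ghost_source": ghost_source}  # type: ignore[attr-defined]
    return sc


def model_14a(p, **kw) -> DemographicScenario:
    return _model_14(p, "ancestral", "model_14a", **kw)


def model_14b(p, **kw) -> DemographicScenario:
    return _model_14(p, "CIII", "model_14b", **kw)


def model_20(p, samples=None, loci=None, locus_scale: float = 1.0) -> DemographicScenario:
    """Clade III Chinese vs North American subclade split at t1."""
    demes = [Deme("CN", p["N_CN"]), Deme("NA", p["N_NA"])]
    events = [Event(time=p["t1"], kind="merge", deme="NA", dest="CN"),
              Event(time=p["t1"], kind="size", deme="CN", value=p["N_ANC"])]
    return DemographicScenario(demes, samples or {"CN": 30, "NA": 9},
                               _loci(p["mu"], loci, locus_scale), events=events,
                               label="model_20")


TEMPLATES = {
    "model_09": model_09,
    "model_10": model_10,
    "model_14a": model_14a,
    "model_14b": model_14b,
    "model_20": model_20,
}
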