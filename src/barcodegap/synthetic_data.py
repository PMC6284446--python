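"""Simulation of taxonomy-structured COI barcode datasets under a K2P process.

Sequences evolve along a four-level tree (root -> subfamily ancestors ->
genus ancestors -> species ancestors -> specimens) under the continuous-time
Kimura 2-parameter substitution process: transition rate alpha, transversion
rate beta per target base, kappa = alpha / beta, with the total rate
alpha + 2*beta scaled so that a branch of length t accrues t expected
substitutions per site.  Sites are independent and identically distributed,
the root sequence is uniform over {A, C, G, T} — exactly the assumptions of
the K2P distance estimator, so parameter recovery is a clean test of the
pipeline.

Each configured divergence is the expected pairwise K2P distance between
the corresponding lineage pair and is split equally over the two connecting
paths: conspecific specimens sit on a star per species (branches
``intra_divergence / 2``), species ancestors on a star per genus
(``congener_divergence / 2``), genus ancestors on a star per subfamily
(``subfamily_divergence / 2``).

The optional *lumped trio* reproduces the known failure mode of barcode
identification: three congeneric species sharing a haplotype.  The three
species share one ancestor sequence, and the first specimen of each is an
exact copy of it, so heterospecific zero-distance ties are guaranteed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_taxa import AlignedBarcode, Dataset, TaxonomyRecord, build_dataset

__all__ = ["SimulationConfig", "evolve_sequence", "simulate_dataset", "transition_probabilities"]

_DECODE = {0: "A", 1: "G", 2: "C", 3: "T"}
_ENCODE = {v: k for k, v in _DECODE.items()}

#: Default specimens-per-species distribution (mean 2.2, as in typical
#: regional barcode surveys: mostly pairs, some singletons, few larger
#: series).  Most multi-specimen species contribute exactly one
#: intraspecific pair, keeping extreme-value noise in the max-intra
#: statistic small.
SPECIMENS_PER_SPECIES_PMF: dict[int, float] = {1: 0.10, 2: 0.65, 3: 0.20, 4: 0.05}


@dataclass
class SimulationConfig:
    """Shape and divergence parameters of a simulated barcode survey.

    Defaults emulate a survey of ~126 species in 7 subfamilies at ~2.2
    specimens per species: intraspecific K2P divergence 0.002 (0.2%),
    congeneric 0.11 (11%), between genera within a subfamily 0.19 (19%),
    658-site barcodes, transition/transversion rate ratio kappa = 2.
    ``specimens_per_species`` may be an int, an inclusive (lo, hi) range, or
    None for the default mean-2.2 distribution.
    """

    n_subfamilies: int = 7
    genera_per_subfamily: int | tuple[int, int] = (4, 8)
    species_per_genus: int | tuple[int, int] = (2, 4)
    specimens_per_species: int | tuple[int, int] | None = None
    seq_length: int = 658
    kappa: float = 2.0
    intra_divergence: float = 0.002
    congener_divergence: float = 0.11
    subfamily_divergence: float = 0.19
    lumped_trio: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (
            0 <= self.intra_divergence
            < self.congener_divergence
            < self.subfamily_divergence
        ):
            raise ValueError(
                "divergences must satisfy intra < congener < subfamily, all >= 0"
            )
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")
        for name in ("n_subfamilies", "genera_per_subfamily", "species_per_genus"):
            v = getattr(self, name)
            lo = v if isinstance(v, int) else v[0]
            if lo < 1:
                raise ValueError(f"{name} must be >= 1")


def transition_probabilities(t: float, kappa: float) -> tuple[float, float, float]:
    """Closed-form K2P substitution probabilities after branch length t.

    Returns ``(p_same, p_transition, p_transversion_each)`` for one site:
    the probability of no net change, of a transitional change, and of each
    of the two transversional target bases.  Rates are normalized so t is in
    expected substitutions/site: beta = 1/(kappa+2), alpha = kappa*beta.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4b = np.exp(-4.0 * beta * t)
    e2ab = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b
    return 1.0 - p_ts - 2.0 * p_tv_each, p_ts, p_tv_each


def _evolve_codes(
    parent: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    p_same, p_ts, p_tv = transition_probabilities(t, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    # outcome per site: [same | transition | transversion 1 | transversion 2]
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    # codes: A=0,G=1 purines; C=2,T=3 pyrimidines. Transition flips within
    # the class (code ^ 1); transversions jump to the other class.
    child[ts_mask] = parent[ts_mask] ^ 1
    other = 2 - 2 * (parent // 2)  # first base of the other class
    child[tv1_mask] = other[tv1_mask]
    child[tv2_mask] = other[tv2_mask] + 1
    return child


def evolve_sequence(
    parent: str, branch_length: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence along one branch under the K2P process."""
    codes = np.fromiter((_ENCODE[c] for c in parent.upper()), dtype=np.int64)
    child = _evolve_codes(codes, branch_length, kappa, rng)
    return "".join(_DECODE[int(c)] for c in child)


def _draw_count(
    value: int | tuple[int, int] | None, rng: np.random.Generator
) -> int:
    if value is None:
        sizes = np.array(sorted(SPECIMENS_PER_SPECIES_PMF))
        probs = np.array([SPECIMENS_PER_SPECIES_PMF[s] for s in sizes])
        return int(rng.choice(sizes, p=probs))
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, dict]:
    """Simulate a full barcode survey; returns (dataset, truth record).

    The truth record holds the configuration, the realized counts, the
    configured gap ratio ``congener_divergence / intra_divergence`` and the
    names of the lumped species (if any).  Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    root = rng.integers(0, 4, size=cfg.seq_length).astype(np.int64)

    barcodes: list[AlignedBarcode] = []
    taxonomy: list[TaxonomyRecord] = []
    lumped_species: list[str] = []
    genus_no = 0

    for sf in range(cfg.n_subfamilies):
        subfamily = f"Subfamily{sf + 1:02d}"
        sf_anc = _evolve_codes(root, cfg.subfamily_divergence / 4.0, cfg.kappa, rng)
        n_genera = _draw_count(cfg.genera_per_subfamily, rng)
        for _ in range(n_genera):
            genus_no += 1
            genus = f"Genus{genus_no:03d}"
            gen_anc = _evolve_codes(
                sf_anc, cfg.subfamily_divergence / 2.0, cfg.kappa, rng
            )
            n_species = _draw_count(cfg.species_per_genus, rng)
            lump_here = cfg.lumped_trio and not lumped_species and n_species >= 3
            shared_anc = None
            if lump_here:
                shared_anc = _evolve_codes(
                    gen_anc, cfg.congener_divergence / 2.0, cfg.kappa, rng
                )
            for sp in range(n_species):
                species = f"{genus} sp{sp + 1:02d}"
                lumped = lump_here and sp < 3
                if lumped:
                    sp_anc = shared_anc
                    lumped_species.append(species)
                else:
                    sp_anc = _evolve_codes(
                        gen_anc, cfg.congener_divergence / 2.0, cfg.kappa, rng
                    )
                n_specimens = _draw_count(cfg.specimens_per_species, rng)
                for m in range(n_specimens):
                    sid = f"{genus}_sp{sp + 1:02d}_{m + 1:02d}"
                    if lumped and m == 0:
                        child = sp_anc.copy()  # exact shared haplotype
                    else:
                        child = _evolve_codes(
                            sp_anc, cfg.intra_divergence / 2.0, cfg.kappa, rng
                        )
                    seq = "".join(_DECODE[int(c)] for c in child)
                    barcodes.append(AlignedBarcode(sid, seq))
                    taxonomy.append(TaxonomyRecord(sid, species, genus, subfamily))

    ds = build_dataset(barcodes, taxonomy)
    truth = {
        "config": asdict(cfg),
        "n_specimens": len(barcodes),
        "n_species": len({r.species for r in taxonomy}),
        "n_genera": genus_no,
        "configured_gap_ratio": (
            cfg.congener_divergence / cfg.intra_divergence
            if cfg.intra_divergence > 0
            else None
        ),
        "lumped_species": lumped_species,
    }
    return ds, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
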