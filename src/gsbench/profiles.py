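"""Bundled simulation profiles for benchmarking without external data.

Each profile couples a population design (SimConfig) with a trait
architecture and a seed, producing a ready-to-use Dataset:

* ``oligogenic``  : 5 large-effect QTL, h2 = 0.5 -- the regime where
                    univariate variable selection is expected to shine.
* ``polygenic``   : 30% of markers carry small effects (infinitesimal-like),
                    h2 = 0.5 -- the regime favoring ridge-type shrinkage.
* ``epistatic``   : oligogenic additive QTL plus pairwise product
                    interactions, h2 = 0.5.
* ``qtlmas-mini`` : the pedigree design of the QTLMAS 2010 population
                    (20 founders, 5 male / 15 female, five chromosomes of
                    100 Mbp, generations F0-F4) at desk scale -- 1,000 markers
                    and 100 offspring per generation instead of the original
                    10,031 markers and ~3,200 individuals -- with a
                    quantitative trait and a thresholded binary trait.
"""

from __future__ import annotations

from .data import Dataset, make_folds
from .simulate import (
    SimConfig,
    assign_trait_architecture,
    binarize_trait,
    simulate_phenotypes,
    simulate_population,
)

PROFILE_NAMES = ("oligogenic", "polygenic", "epistatic", "qtlmas-mini")


def make_profile(
    name: str,
    seed: int = 0,
    n_markers: int | None = None,
    offspring_per_generation: int | None = None,
    k_folds: int = 10,
) -> Dataset:
    """Simulate the named profile into a Dataset with precomputed folds.

    ``n_markers`` and ``offspring_per_generation`` override the profile
    defaults to scale the problem up or down; the trait architecture scales
    with them.
    """
    if name not in PROFILE_NAMES:
        raise ValueError(f"unknown profile {name!r}; known: {PROFILE_NAMES}")
    cfg = SimConfig(
        n_markers=n_markers if n_markers is not None else 1000,
        offspring_per_generation=(
            offspring_per_generation if offspring_per_generation is not None else 100
        ),
        seed=seed,
    )
    g, ped = simulate_population(cfg)
    kind = "oligogenic" if name == "qtlmas-mini" else name
    if name == "qtlmas-mini":
        kind = "epistatic"  # QTLMAS trait 1 carries epistasis
    arch = assign_trait_architecture(g, kind=kind, target_h2=0.5, seed=seed + 1)
    pheno, truth = simulate_phenotypes(g, arch, seed=seed + 2)
    phenotypes = {"trait1": pheno}
    if name == "qtlmas-mini":
        phenotypes["trait2_binary"] = binarize_trait(pheno, 0.5)
    folds = make_folds(g.sample_ids, k=k_folds, seed=seed + 3)
    ds = Dataset(genotypes=g, phenotypes=phenotypes, folds=folds, name=name)
    ds.truth = truth  # realized genetic values for oracle checks
    ds.architecture = arch
    ds.pedigree = ped
    return ds
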