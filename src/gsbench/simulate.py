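"""Forward-in-time pedigree simulator for genomic-selection benchmarks.

Emulates the structure of the QTLMAS 2010 workshop population: a small founder
group (5 males, 15 females), several discrete offspring generations produced by
random sire/dam mating, five chromosomes with a uniform 1 cM/Mbp genetic map,
biallelic SNPs, and traits with known additive (and optionally epistatic)
architecture at a tunable narrow-sense heritability.  A binary trait is
obtained by thresholding the continuous liability.

Recombination follows the Haldane model: crossover counts are Poisson with
mean equal to the chromosome length in Morgans and crossover positions are
uniform (no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeVector

MORGAN_PER_BP = 1e-8  # 1 cM per Mbp


@dataclass
class SimConfig:
    """Population design parameters (defaults: the 'qtlmas-mini' profile)."""

    n_founders: int = 20
    founders_male: int = 5
    founders_female: int = 15
    n_generations: int = 4
    offspring_per_generation: int = 100
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    n_markers: int = 1000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders_male + self.founders_female != self.n_founders:
            raise ValueError("founders_male + founders_female must equal n_founders")
        low, high = self.founder_maf_range
        if not 0 < low <= high <= 0.5:
            raise ValueError("founder_maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_generations > 0 and (
            self.founders_male == 0 or self.founders_female == 0
        ):
            raise ValueError("need founders of both sexes to breed offspring")


@dataclass
class Pedigree:
    """Per-individual id, sire, dam and generation index (founders: gen 0)."""

    ids: list[str]
    sire: list[str | None]
    dam: list[str | None]
    generation: list[int]
    sex: list[str] = field(default_factory=list)  # 'M' / 'F'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [s if s is not None else "NA" for s in self.sire],
                "dam": [d if d is not None else "NA" for d in self.dam],
                "generation": self.generation,
                "sex": self.sex,
            }
        )


@dataclass
class TraitArchitecture:
    """Known trait architecture: additive QTL, epistatic pairs, target h2."""

    additive_qtl: list[tuple[int, float]]
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    target_h2: float = 0.5
    binary: bool = False
    liability_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.target_h2 <= 1:
            raise ValueError("target_h2 must be in [0, 1]")
        for i, j, _ in self.epistatic_pairs:
            if i == j:
                raise ValueError("epistatic pairs must involve two distinct markers")


def _marker_map(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced marker positions; remainder markers go to the first
    chromosomes (deterministic)."""
    base, rem = divmod(cfg.n_markers, cfg.n_chromosomes)
    chrom, pos = [], []
    for c in range(cfg.n_chromosomes):
        m = base + (1 if c < rem else 0)
        if m == 0:
            continue
        p = np.linspace(1, cfg.chrom_length_bp, m).astype(np.int64)
        chrom.extend([f"chr{c + 1}"] * m)
        pos.append(p)
    return np.array(chrom), np.concatenate(pos)


def _gamete(
    haps: np.ndarray,
    chrom_starts: np.ndarray,
    chrom_pos_morgans: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine one parent's two haplotypes into a gamete (Haldane model)."""
    out = np.empty(haps.shape[1], dtype=np.int8)
    for c, pos_m in enumerate(chrom_pos_morgans):
        start, stop = chrom_starts[c], chrom_starts[c + 1]
        if stop == start:
            continue
        length = pos_m[-1] - pos_m[0]
        n_x = rng.poisson(length)
        cuts = np.sort(rng.uniform(pos_m[0], pos_m[-1], size=n_x))
        phase = (np.searchsorted(cuts, pos_m) + rng.integers(2)) % 2
        seg = haps[:, start:stop]
        out[start:stop] = np.where(phase == 0, seg[0], seg[1])
    return out


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, Pedigree]:
    """Simulate founder haplotypes and breed discrete offspring generations.

    Founder alleles are drawn per marker as Bernoulli(p) with the allele
    frequency p ~ Uniform(founder_maf_range); offspring are produced by random
    sire/dam mating (with replacement) within the previous generation.
    Fully deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _marker_map(cfg)
    p_marker = rng.uniform(*cfg.founder_maf_range, size=len(pos))

    # boundaries of each chromosome's marker block in column order
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    starts = [0]
    for c in chrom_names:
        starts.append(starts[-1] + int((chrom == c).sum()))
    chrom_starts = np.array(starts)
    chrom_pos_m = [
        pos[chrom_starts[c] : chrom_starts[c + 1]] * MORGAN_PER_BP
        for c in range(cfg.n_chromosomes)
    ]

    n_markers = len(pos)
    haplotypes = []  # (2, n_markers) per individual
    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    gens: list[int] = []
    sexes: list[str] = []

    for i in range(cfg.n_founders):
        haplotypes.append(
            (rng.random((2, n_markers)) < p_marker).astype(np.int8)
        )
        ids.append(f"F0_{i + 1}")
        sires.append(None)
        dams.append(None)
        gens.append(0)
        sexes.append("M" if i < cfg.founders_male else "F")

    prev_slice = slice(0, cfg.n_founders)
    for gen in range(1, cfg.n_generations + 1):
        prev_ids = ids[prev_slice]
        prev_sex = sexes[prev_slice]
        males = [i for i, s in enumerate(prev_sex) if s == "M"]
        females = [i for i, s in enumerate(prev_sex) if s == "F"]
        if not males or not females:
            raise ValueError(f"generation {gen - 1} lacks one sex; cannot breed")
        first = len(ids)
        offspring_sex = rng.integers(2, size=cfg.offspring_per_generation)
        if offspring_sex.min() == offspring_sex.max():  # force both sexes present
            offspring_sex[0] = 1 - offspring_sex[0]
        for o in range(cfg.offspring_per_generation):
            si = males[rng.integers(len(males))]
            di = females[rng.integers(len(females))]
            pat = _gamete(haplotypes[prev_slice.start + si], chrom_starts, chrom_pos_m, rng)
            mat = _gamete(haplotypes[prev_slice.start + di], chrom_starts, chrom_pos_m, rng)
            haplotypes.append(np.stack([pat, mat]))
            ids.append(f"F{gen}_{o + 1}")
            sires.append(prev_ids[si])
            dams.append(prev_ids[di])
            gens.append(gen)
            sexes.append("M" if offspring_sex[o] == 0 else "F")
        prev_slice = slice(first, len(ids))

    values = np.stack([h.sum(axis=0) for h in haplotypes]).astype(np.int16)
    g = GenotypeMatrix(
        values=values, sample_ids=ids, marker_ids=[f"m{j + 1}" for j in range(n_markers)],
        chrom=chrom, pos=pos,
    )
    ped = Pedigree(ids=ids, sire=sires, dam=dams, generation=gens, sex=sexes)
    return g, ped


def assign_trait_architecture(
    g: GenotypeMatrix,
    kind: str = "oligogenic",
    n_qtl: int | None = None,
    target_h2: float = 0.5,
    n_epistatic_pairs: int | None = None,
    seed: int = 0,
) -> TraitArchitecture:
    """Draw a trait architecture of the requested kind.

    oligogenic: few QTL (default 5) with large N(0,1) effects.
    polygenic: many QTL (default 30% of markers) with N(0, 1/n_qtl) effects.
    epistatic: oligogenic additive QTL plus product-interaction pairs.
    """
    rng = np.random.default_rng(seed)
    p = g.n_markers
    if kind not in ("oligogenic", "polygenic", "epistatic"):
        raise ValueError(f"unknown architecture kind {kind!r}")
    if n_qtl is None:
        n_qtl = 5 if kind in ("oligogenic", "epistatic") else max(1, int(0.3 * p))
    if n_qtl > p:
        raise ValueError("n_qtl exceeds marker count")
    qtl_idx = rng.choice(p, size=n_qtl, replace=False)
    if kind == "polygenic":
        effects = rng.normal(0.0, np.sqrt(1.0 / n_qtl), size=n_qtl)
    else:
        effects = rng.normal(0.0, 1.0, size=n_qtl)
    pairs: list[tuple[int, int, float]] = []
    if kind == "epistatic":
        n_pairs = n_epistatic_pairs if n_epistatic_pairs is not None else max(1, n_qtl // 2)
        for _ in range(n_pairs):
            i, j = rng.choice(p, size=2, replace=False)
            pairs.append((int(i), int(j), float(rng.normal(0.0, 1.0))))
    return TraitArchitecture(
        additive_qtl=[(int(i), float(e)) for i, e in zip(qtl_idx, effects)],
        epistatic_pairs=pairs,
        target_h2=target_h2,
    )


def simulate_phenotypes(
    g: GenotypeMatrix, arch: TraitArchitecture, seed: int = 0
) -> tuple[PhenotypeVector, dict]:
    """Generate phenotypes y = G + e with e calibrated to the target h2.

    The genetic value is G_i = sum_k a_k x_ik + sum_(i,j) w_ij x_i x_j using
    raw (uncentered) dosage products for the epistatic terms.  The noise
    variance solves Var(additive)/(Var(additive) + sigma_e2) = target_h2.
    Returns the phenotype and a dict of realized components for oracle tests:
    'genetic_values', 'additive_values', 'sigma_e2'.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(g.values, dtype=float)
    n = g.n_samples
    additive = np.zeros(n)
    for idx, eff in arch.additive_qtl:
        if not 0 <= idx < g.n_markers:
            raise ValueError(f"QTL index {idx} out of range")
        additive += eff * X[:, idx]
    epi = np.zeros(n)
    for i, j, eff in arch.epistatic_pairs:
        epi += eff * X[:, i] * X[:, j]
    genetic = additive + epi
    var_add = float(np.var(additive))
    h2 = arch.target_h2
    if h2 > 0:
        if not arch.additive_qtl:
            raise ValueError("target_h2 > 0 requires at least one additive QTL")
        if var_add <= 0:
            raise ValueError(
                "additive genetic variance is zero (all QTL monomorphic?); "
                "cannot calibrate noise for target_h2 > 0"
            )
        sigma_e2 = var_add * (1.0 - h2) / h2
    else:
        sigma_e2 = 1.0
    noise = rng.normal(0.0, np.sqrt(sigma_e2), size=n) if sigma_e2 > 0 else np.zeros(n)
    y = genetic + noise
    pheno = PhenotypeVector(trait_name="sim_trait", values=y)
    truth = {
        "genetic_values": genetic,
        "additive_values": additive,
        "epistatic_values": epi,
        "sigma_e2": sigma_e2,
        "var_additive": var_add,
    }
    return pheno, truth


def binarize_trait(y: PhenotypeVector, threshold_quantile: float = 0.5) -> PhenotypeVector:
    """Liability-threshold binary trait: 1 above the empirical quantile."""
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    v = np.asarray(y.values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size == 0 or np.ptp(obs) == 0:
        raise ValueError("cannot threshold a constant (or empty) liability")
    cut = np.quantile(obs, threshold_quantile)
    out = np.where(np.isnan(v), np.nan, (v > cut).astype(float))
    return PhenotypeVector(trait_name=f"{y.trait_name}_binary", values=out, binary=True)


def write_truth(truth: dict, arch: TraitArchitecture, sample_ids, path) -> None:
    """Write QTL effects and true genetic values as TSV for oracle checks."""
    rows = [("additive", i, None, e) for i, e in arch.additive_qtl]
    rows += [("epistatic", i, j, e) for i, j, e in arch.epistatic_pairs]
    pd.DataFrame(rows, columns=["kind", "marker_i", "marker_j", "effect"]).to_csv(
        str(path) + ".qtl.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"sample_id": list(sample_ids), "genetic_value": truth["genetic_values"]}
    ).to_csv(str(path) + ".gv.tsv", sep="\t", index=False)
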