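"""Synthetic sequence-function datasets for desk-scale experiments.

Two generators emulate the statistical shape of the benchmark tasks this
package is built around, without requiring any external download:

* :func:`generate_landscape` — a combinatorial mutagenesis library around a
  short wild type, with continuous fitness from an additive plus sparse
  pairwise-epistatic landscape and Gaussian measurement noise. This mirrors
  a saturation-mutagenesis regression task (a handful of mutated positions,
  fitness known for every variant).
* :func:`generate_binder_dataset` — the same latent landscape thresholded
  into binder / non-binder classes, with the threshold calibrated to a
  target positive fraction. This mirrors an antibody CDR library screened
  for antigen binding.

Both are fully seeded and deterministic. The presets are a stated world:
wild-type length 9, four mutated positions and ~3,000 variants for the
landscape (the data regime where augmentation matters most), and a
9-position binder library for the classification task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_model import AMINO_ACIDS
from .dataset import LabeledDataset, LabeledRecord
from .errors import CapacityError, ConfigError

__all__ = [
    "LandscapeSpec",
    "BinderSpec",
    "generate_landscape",
    "generate_binder_dataset",
    "gb1_like_spec",
    "cdrh3_like_spec",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """An additive + pairwise-epistatic fitness landscape over a mutagenized region.

    ``additive_effects[p][r]`` is the fitness contribution of residue ``r`` at
    mutated position ``p`` (wild-type residues contribute 0);
    ``pairwise_effects[((p1, p2), (r1, r2))]`` adds epistasis for particular
    double substitutions. Labels are the sum of applicable effects plus
    ``N(0, noise_sd)`` noise.
    """

    wild_type: str
    mutated_positions: tuple[int, ...]
    alphabet_per_position: dict[int, tuple[str, ...]]
    additive_effects: dict[int, dict[str, float]]
    pairwise_effects: dict[tuple[tuple[int, int], tuple[str, str]], float]
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.wild_type)
        if any(not 0 <= p < L for p in self.mutated_positions):
            raise ConfigError("mutated_positions must index into the wild type")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def latent_fitness(self, sequence: str) -> float:
        """Noise-free fitness of a variant (0 for the wild type)."""
        subs = {
            p: sequence[p]
            for p in self.mutated_positions
            if sequence[p] != self.wild_type[p]
        }
        value = sum(self.additive_effects.get(p, {}).get(r, 0.0) for p, r in subs.items())
        for ((p1, p2), (r1, r2)), eff in self.pairwise_effects.items():
            if subs.get(p1) == r1 and subs.get(p2) == r2:
                value += eff
        return value


@dataclass(frozen=True)
class BinderSpec(LandscapeSpec):
    """Landscape spec plus a binary threshold on latent fitness.

    When ``target_positive_fraction`` is set the threshold is calibrated to
    the matching quantile of the generated latent fitness values; otherwise
    the explicit ``threshold`` is used.
    """

    threshold: float | None = None
    target_positive_fraction: float | None = 0.5

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.target_positive_fraction is not None and not (
            0.0 < self.target_positive_fraction < 1.0
        ):
            raise ConfigError("target_positive_fraction must be in (0, 1)")
        if self.threshold is None and self.target_positive_fraction is None:
            raise ConfigError("either threshold or target_positive_fraction is required")


def _n_variants_at_ed(spec: LandscapeSpec, ed: int) -> int:
    """Count distinct variants with exactly `ed` substitutions."""
    alts = [
        sum(1 for a in spec.alphabet_per_position[p] if a != spec.wild_type[p])
        for p in spec.mutated_positions
    ]
    if ed == 0:
        return 1
    if ed > len(alts):
        return 0
    # alternatives counts are equal in the presets; use exact product over combos
    total = 0
    from itertools import combinations

    for combo in combinations(range(len(alts)), ed):
        prod = 1
        for i in combo:
            prod *= alts[i]
        total += prod
    return total


def _sample_variants(
    spec: LandscapeSpec, n_variants: int, max_ed: int, rng: np.random.Generator
) -> list[str]:
    """Sample distinct variants spanning edit distances 1..max_ed."""
    positions = list(spec.mutated_positions)
    max_ed = min(max_ed, len(positions))
    avail = {ed: _n_variants_at_ed(spec, ed) for ed in range(1, max_ed + 1)}
    total_avail = sum(avail.values())
    if n_variants > total_avail:
        raise CapacityError(
            f"requested {n_variants} variants but only {total_avail} exist "
            f"within edit distance {max_ed}"
        )
    # Apportion the request across edit distances by sqrt(availability):
    # availability grows combinatorially with distance, and linear weighting
    # would starve the near-wild-type strata that form the training side of
    # an edit-distance split. Sqrt damping keeps every distance represented
    # at roughly the near/far proportions of real combinatorial libraries.
    weights = {ed: float(np.sqrt(avail[ed])) for ed in avail}
    w_total = sum(weights.values())
    quotas = {
        ed: min(avail[ed], max(1, round(n_variants * weights[ed] / w_total)))
        for ed in avail
    }
    while sum(quotas.values()) != n_variants:
        diff = n_variants - sum(quotas.values())
        step = 1 if diff > 0 else -1
        # adjust the largest stratum with slack
        candidates = [
            ed for ed in sorted(avail, key=lambda e: -avail[e])
            if (step > 0 and quotas[ed] < avail[ed]) or (step < 0 and quotas[ed] > 1)
        ]
        quotas[candidates[0]] += step

    variants: list[str] = []
    seen = {spec.wild_type}
    wt = list(spec.wild_type)
    for ed, quota in quotas.items():
        exhaustive = avail[ed] <= 4 * quota and avail[ed] <= 50_000
        if exhaustive:
            pool = _enumerate_at_ed(spec, ed)
            idx = rng.choice(len(pool), size=quota, replace=False)
            chosen = [pool[i] for i in idx]
        else:
            chosen = []
            guard = 0
            while len(chosen) < quota:
                guard += 1
                if guard > 1000 * quota:  # pragma: no cover - safety valve
                    raise CapacityError(f"could not sample {quota} variants at ED {ed}")
                pos = rng.choice(len(positions), size=ed, replace=False)
                seq = wt.copy()
                for i in pos:
                    p = positions[int(i)]
                    alts = [a for a in spec.alphabet_per_position[p] if a != spec.wild_type[p]]
                    seq[p] = alts[int(rng.integers(len(alts)))]
                s = "".join(seq)
                if s not in seen:
                    seen.add(s)
                    chosen.append(s)
        for s in chosen:
            seen.add(s)
        variants.extend(chosen)
    return variants


def _enumerate_at_ed(spec: LandscapeSpec, ed: int) -> list[str]:
    from itertools import combinations, product

    wt = spec.wild_type
    out = []
    positions = list(spec.mutated_positions)
    for combo in combinations(positions, ed):
        alts_lists = [
            [a for a in spec.alphabet_per_position[p] if a != wt[p]] for p in combo
        ]
        for residues in product(*alts_lists):
            seq = list(wt)
            for p, r in zip(combo, residues):
                seq[p] = r
            out.append("".join(seq))
    return out


def generate_landscape(
    spec: LandscapeSpec, n_variants: int, max_ed: int
) -> LabeledDataset:
    """Generate a regression dataset of distinct variants labeled by noisy fitness.

    The edit-distance spectrum spans 1..max_ed (each distance is represented)
    so downstream edit-distance splitting yields non-degenerate partitions.
    Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    variants = _sample_variants(spec, n_variants, max_ed, rng)
    noise = (
        rng.normal(0.0, spec.noise_sd, size=len(variants))
        if spec.noise_sd > 0
        else np.zeros(len(variants))
    )
    records = [
        LabeledRecord(id=f"v{i}", sequence=s, label=spec.latent_fitness(s) + float(noise[i]))
        for i, s in enumerate(variants)
    ]
    return LabeledDataset(records, alphabet="amino_acid", task="regression")


def generate_binder_dataset(
    spec: BinderSpec, n_variants: int, max_ed: int
) -> LabeledDataset:
    """Generate a binder/non-binder classification dataset.

    Latent fitness is computed as in :func:`generate_landscape` (noise
    included); the binary label is 1 where latent fitness exceeds the
    threshold. With ``target_positive_fraction`` set, the threshold is the
    matching empirical quantile, so the positive count lands within one
    record of the target.
    """
    rng = np.random.default_rng(spec.seed)
    variants = _sample_variants(spec, n_variants, max_ed, rng)
    noise = (
        rng.normal(0.0, spec.noise_sd, size=len(variants))
        if spec.noise_sd > 0
        else np.zeros(len(variants))
    )
    latent = np.array(
        [spec.latent_fitness(s) + float(noise[i]) for i, s in enumerate(variants)]
    )
    if spec.target_positive_fraction is not None:
        threshold = float(np.quantile(latent, 1.0 - spec.target_positive_fraction))
    else:
        threshold = float(spec.threshold)
    records = [
        LabeledRecord(id=f"v{i}", sequence=s, label=float(latent[i] > threshold))
        for i, s in enumerate(variants)
    ]
    return LabeledDataset(records, alphabet="amino_acid", task="classification")


# ---------------------------------------------------------------------------
# Presets (a stated world: fixed scales, effects drawn once per seed)
# ---------------------------------------------------------------------------

_WT9 = "MQYKLVING"  # arbitrary 9-residue wild type used by both presets


def _draw_effects(
    positions: tuple[int, ...],
    alphabet: dict[int, tuple[str, ...]],
    wild_type: str,
    rng: np.random.Generator,
    additive_sd: float = 1.0,
    pairwise_sd: float = 0.5,
    pairwise_per_pair: int = 30,
) -> tuple[dict, dict]:
    additive = {
        p: {
            r: float(rng.normal(0.0, additive_sd))
            for r in alphabet[p]
            if r != wild_type[p]
        }
        for p in positions
    }
    pairwise = {}
    from itertools import combinations

    for p1, p2 in combinations(positions, 2):
        alts1 = [r for r in alphabet[p1] if r != wild_type[p1]]
        alts2 = [r for r in alphabet[p2] if r != wild_type[p2]]
        for _ in range(pairwise_per_pair):
            r1 = alts1[int(rng.integers(len(alts1)))]
            r2 = alts2[int(rng.integers(len(alts2)))]
            pairwise[((p1, p2), (r1, r2))] = float(rng.normal(0.0, pairwise_sd))
    return additive, pairwise


def gb1_like_spec(seed: int = 0, noise_sd: float = 0.1) -> LandscapeSpec:
    """Desk-scale saturation-mutagenesis landscape: 9-mer wild type, 4 fully
    mutable positions (20 residues each), sparse pairwise epistasis."""
    positions = (2, 4, 6, 8)
    alphabet = {p: AMINO_ACIDS for p in positions}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    additive, pairwise = _draw_effects(positions, alphabet, _WT9, rng)
    return LandscapeSpec(
        wild_type=_WT9,
        mutated_positions=positions,
        alphabet_per_position=alphabet,
        additive_effects=additive,
        pairwise_effects=pairwise,
        noise_sd=noise_sd,
        seed=seed,
    )


def cdrh3_like_spec(
    seed: int = 0,
    noise_sd: float = 0.1,
    target_positive_fraction: float = 0.5,
) -> BinderSpec:
    """Desk-scale binder library: all 9 positions of the 9-mer mutable over a
    reduced 8-residue alphabet, thresholded to the target positive fraction."""
    positions = tuple(range(9))
    alphabet = {p: tuple("ACDFGKLS") for p in positions}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    additive, pairwise = _draw_effects(
        positions, alphabet, _WT9, rng, pairwise_per_pair=10
    )
    return BinderSpec(
        wild_type=_WT9,
        mutated_positions=positions,
        alphabet_per_position=alphabet,
        additive_effects=additive,
        pairwise_effects=pairwise,
        noise_sd=noise_sd,
        seed=seed,
        target_positive_fraction=target_positive_fraction,
    )
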