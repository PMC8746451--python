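"""Construction of class-imbalanced train/test pair datasets.

Two sampling regimes are supported.  In the *Full* regime, labeled pairs for
training and testing are sampled from all proteins with disjointness enforced
at the unordered-pair level only, the construction most of the PPI-prediction
literature uses.  In the *Held-Out* regime the proteins are split into bins
and one or two bins are reserved exclusively for test pairs, so that no test
protein ever appears in a training pair (the protein-disjoint "C3" regime).
Positive pairs come from a known interaction set; negatives are random
non-interacting pairs, reflecting that experimentally confirmed
non-interactions do not exist at scale.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io_formats import (
    CapacityError,
    InteractionSet,
    Proteome,
    canonical_pair,
)

Pair = tuple[str, str]


@dataclass
class PairDataset:
    """Labeled protein pairs with a declared class ratio and split role."""

    pairs: list[Pair]
    labels: np.ndarray
    role: str = "train"            # train | test
    regime: str = "full"           # full | held_out
    positive_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        unordered = {canonical_pair(*p) for p in self.pairs}
        if len(unordered) != len(self.pairs):
            raise ValueError("duplicate unordered pair within dataset")
        if len(self.pairs):
            observed = float(np.mean(self.labels))
            if abs(observed - self.positive_fraction) > 1.0 / len(self.pairs) + 1e-12:
                raise ValueError(
                    f"declared positive_fraction {self.positive_fraction} "
                    f"differs from observed {observed:.6f}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self.pairs) - self.n_positive

    def proteins(self) -> set[str]:
        return {p for pair in self.pairs for p in pair}

    def pair_set(self) -> set[Pair]:
        return {canonical_pair(*p) for p in self.pairs}

    def subset(self, idx: np.ndarray, role: str | None = None) -> "PairDataset":
        pairs = [self.pairs[i] for i in idx]
        labels = self.labels[idx]
        frac = float(labels.mean()) if len(labels) else 0.0
        return PairDataset(pairs, labels, role=role or self.role,
                           regime=self.regime, positive_fraction=frac)


@dataclass
class RatioSpec:
    """A positive-class ratio plus the counts that realize it.

    Either ``total`` (positive + negative) or nothing besides ``n_positive``
    may be given; when ``total`` is absent the negative count is derived as
    ``round(n_pos * (1 - f) / f)``.  ``n_positive="all"`` means "use every
    available positive pair" (the convention for held-out 1:1 and 1:9 test
    sets).
    """

    positive_fraction: float
    n_positive: int | str = "all"
    total: int | None = None

    def resolve(self, available_positives: int) -> tuple[int, int]:
        """Return concrete ``(n_positive, n_negative)`` counts."""
        f = self.positive_fraction
        if not (0.0 < f <= 1.0):
            raise ValueError("positive_fraction must be in (0, 1]")
        if self.n_positive == "all":
            n_pos = available_positives
        else:
            n_pos = int(self.n_positive)
        if n_pos > available_positives:
            raise CapacityError(
                f"requested {n_pos} positives, only {available_positives} available")
        if self.total is not None:
            n_neg = self.total - n_pos
        else:
            n_neg = int(round(n_pos * (1.0 - f) / f))
        if n_neg < 0:
            raise ValueError("implied negative count is negative")
        return n_pos, n_neg


@dataclass
class HeldOutConfig:
    """A partition of proteins into near-equal bins with some bins held out."""

    n_bins: int
    held_bins: frozenset[int]
    bin_assignment: dict[str, int]

    def __post_init__(self) -> None:
        self.held_bins = frozenset(self.held_bins)
        if not self.held_bins <= set(range(self.n_bins)):
            raise ValueError("held_bins outside bin range")
        sizes = self.bin_sizes()
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("bins are not near-equal sized")

    def bin_sizes(self) -> list[int]:
        sizes = [0] * self.n_bins
        for b in self.bin_assignment.values():
            sizes[b] += 1
        return sizes

    def held_proteins(self) -> set[str]:
        return {p for p, b in self.bin_assignment.items() if b in self.held_bins}

    def training_proteins(self) -> set[str]:
        return {p for p, b in self.bin_assignment.items()
                if b not in self.held_bins}


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_negative_pairs(proteome: Proteome | list[str],
                          known_positives: InteractionSet,
                          n: int,
                          rng_seed: int | np.random.Generator,
                          exclude: set[Pair] | None = None) -> list[Pair]:
    """Draw ``n`` distinct random unordered pairs that are not known positives.

    ``proteome`` may be a Proteome or an explicit list of protein identifiers
    defining the sampling universe.  Pairs in ``exclude`` (already-sampled
    negatives of another split) are also avoided.  Deterministic under seed.
    """
    ids = sorted(proteome.records) if isinstance(proteome, Proteome) else sorted(proteome)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if n == 0:
        return []
    universe = set(ids)
    forbidden = {canonical_pair(*p) for p in known_positives}
    if exclude:
        forbidden |= {canonical_pair(*p) for p in exclude}
    # only pairs inside the sampling universe reduce capacity
    forbidden = {(a, b) for a, b in forbidden
                 if a in universe and b in universe}
    total_space = len(ids) * (len(ids) - 1) // 2
    capacity = total_space - len(forbidden)
    if n > capacity:
        raise CapacityError(
            f"requested {n} negative pairs but only {capacity} of "
            f"{total_space} unordered pairs are available")
    chosen: set[Pair] = set()
    # Rejection sampling, falling back to exhaustive enumeration when the
    # request saturates the pair space.
    if n <= 0.5 * capacity:
        max_tries = 50 * n + 1000
        tries = 0
        while len(chosen) < n and tries < max_tries:
            need = n - len(chosen)
            ia = rng.integers(0, len(ids), size=2 * need + 8)
            ib = rng.integers(0, len(ids), size=2 * need + 8)
            for x, y in zip(ia, ib):
                if x == y:
                    continue
                pair = canonical_pair(ids[x], ids[y])
                if pair in forbidden or pair in chosen:
                    continue
                chosen.add(pair)
                if len(chosen) == n:
                    break
            tries += 1
        if len(chosen) == n:
            return sorted(chosen)
        chosen = set()  # fall through to enumeration
    all_pairs = [canonical_pair(ids[i], ids[j])
                 for i in range(len(ids)) for j in range(i + 1, len(ids))]
    available = [p for p in all_pairs if p not in forbidden]
    idx = rng.choice(len(available), size=n, replace=False)
    return sorted(available[i] for i in idx)


def _sample_positive_pairs(interactions: InteractionSet, n: int,
                           rng: np.random.Generator,
                           exclude: set[Pair] | None = None) -> list[Pair]:
    pool = [p for p in interactions.sorted_pairs()
            if not exclude or canonical_pair(*p) not in exclude]
    if n > len(pool):
        raise CapacityError(f"requested {n} positives, only {len(pool)} available")
    idx = rng.choice(len(pool), size=n, replace=False)
    return sorted(pool[i] for i in idx)


def _assemble(pos: list[Pair], neg: list[Pair], role: str, regime: str,
              rng: np.random.Generator) -> PairDataset:
    pairs = list(pos) + list(neg)
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=int)
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    labels = labels[order]
    frac = float(labels.mean()) if len(labels) else 0.0
    return PairDataset(pairs, labels, role=role, regime=regime,
                       positive_fraction=frac)


def build_full_datasets(proteome: Proteome,
                        interactions: InteractionSet,
                        train_spec: RatioSpec,
                        test_spec: RatioSpec,
                        rng_seed: int) -> tuple[PairDataset, PairDataset]:
    """Build non-overlapping train and test datasets under the Full regime.

    Positives are drawn from the interaction set and negatives from random
    non-interacting pairs; train and test are disjoint as unordered pair sets
    for both classes, but proteins are freely shared between the splits.
    """
    rng = np.random.default_rng(rng_seed)
    n_pos_tr, n_neg_tr = train_spec.resolve(len(interactions))
    train_pos = _sample_positive_pairs(interactions, n_pos_tr, rng)
    n_pos_te, n_neg_te = test_spec.resolve(len(interactions) - n_pos_tr)
    test_pos = _sample_positive_pairs(interactions, n_pos_te, rng,
                                      exclude=set(train_pos))
    train_neg = sample_negative_pairs(proteome, interactions, n_neg_tr, rng)
    test_neg = sample_negative_pairs(proteome, interactions, n_neg_te, rng,
                                     exclude=set(train_neg))
    train = _assemble(train_pos, train_neg, "train", "full", rng)
    test = _assemble(test_pos, test_neg, "test", "full", rng)
    return train, test


def stratified_folds(dataset: PairDataset, k: int = 5,
                     rng_seed: int = 0) -> list[tuple[PairDataset, PairDataset]]:
    """Stratified k-fold splits preserving the class ratio per fold."""
    if k < 2:
        raise ValueError("k must be >= 2 for cross-validation")
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class must have >= {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    out = []
    x = np.zeros(len(dataset))
    for train_idx, test_idx in skf.split(x, dataset.labels):
        out.append((dataset.subset(train_idx, role="train"),
                    dataset.subset(test_idx, role="test")))
    return out


# ---------------------------------------------------------------------------
# Held-out regime
# ---------------------------------------------------------------------------

def assign_heldout_bins(proteome: Proteome | list[str], n_bins: int = 6,
                        rng_seed: int = 0) -> HeldOutConfig:
    """Randomly chunk the proteins into near-equal bins.

    Remainders after the near-equal split go to the lowest-index bins, so bin
    sizes differ by at most one.
    """
    ids = sorted(proteome.records) if isinstance(proteome, Proteome) else sorted(proteome)
    if len(ids) < n_bins:
        raise ValueError("fewer proteins than bins")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(ids))
    base, rem = divmod(len(ids), n_bins)
    assignment: dict[str, int] = {}
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        for i in perm[start:start + size]:
            assignment[ids[i]] = b
        start += size
    return HeldOutConfig(n_bins=n_bins, held_bins=frozenset(),
                         bin_assignment=assignment)


def enumerate_heldout_configs(n_bins: int = 6) -> list[frozenset[int]]:
    """All ways of holding out 1 or 2 of the bins (21 for 6 bins).

    Deterministic order: singletons ascending, then pairs lexicographic.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    singles = [frozenset({i}) for i in range(n_bins)]
    pairs = [frozenset(c) for c in itertools.combinations(range(n_bins), 2)]
    return singles + pairs


def build_heldout_datasets(proteome: Proteome,
                           interactions: InteractionSet,
                           config: HeldOutConfig,
                           train_spec: RatioSpec,
                           test_spec: RatioSpec,
                           rng_seed: int) -> tuple[PairDataset, PairDataset]:
    """Build protein-disjoint train and test datasets.

    Every training pair has both proteins outside the held bins and every test
    pair has both proteins inside them, so test proteins are entirely unseen
    during training.  Test positives default to all interactions among held
    proteins (``n_positive="all"``); heavily imbalanced specs may cap them.
    Negatives are sampled within the respective protein universes.
    """
    if not config.held_bins:
        raise ValueError("config.held_bins is empty")
    held = config.held_proteins()
    training = config.training_proteins()
    test_pos_all = InteractionSet(
        (p for p in interactions if p[0] in held and p[1] in held),
        provenance="held-out positives")
    train_pos_all = InteractionSet(
        (p for p in interactions if p[0] in training and p[1] in training),
        provenance="training positives")
    rng = np.random.default_rng(rng_seed)

    n_pos_tr, n_neg_tr = train_spec.resolve(len(train_pos_all))
    train_pos = _sample_positive_pairs(train_pos_all, n_pos_tr, rng)
    try:
        n_pos_te, n_neg_te = test_spec.resolve(len(test_pos_all))
    except CapacityError as exc:
        raise CapacityError(
            f"held bins {sorted(config.held_bins)} contain "
            f"{len(test_pos_all)} positive pairs: {exc}") from exc
    test_pos = _sample_positive_pairs(test_pos_all, n_pos_te, rng)

    train_neg = sample_negative_pairs(sorted(training), interactions,
                                      n_neg_tr, rng)
    test_neg = sample_negative_pairs(sorted(held), interactions, n_neg_te, rng)
    train = _assemble(train_pos, train_neg, "train", "held_out", rng)
    test = _assemble(test_pos, test_neg, "test", "held_out", rng)
    return train, test


def count_unique_proteins(pairs: list[Pair]) -> int:
    """Number of distinct proteins among the endpoints of a pair list."""
    return len({p for pair in pairs for p in pair})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_pair_dataset(dataset: PairDataset, path: str | Path,
                       manifest: dict | None = None) -> None:
    """Write pairs + labels as TSV with a JSON side-car manifest."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tlabel\n")
        for (a, b), y in zip(dataset.pairs, dataset.labels):
            fh.write(f"{a}\t{b}\t{int(y)}\n")
    meta = {"role": dataset.role, "regime": dataset.regime,
            "positive_fraction": dataset.positive_fraction,
            "n_pairs": len(dataset)}
    if manifest:
        meta.update(manifest)
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str))


def read_pair_dataset(path: str | Path) -> PairDataset:
    path = Path(path)
    pairs: list[Pair] = []
    labels: list[int] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_a", "protein_b", "label"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            if not line.strip():
                continue
            a, b, y = line.rstrip("\n").split("\t")[:3]
            pairs.append((a, b))
            labels.append(int(y))
    meta_path = path.with_suffix(path.suffix + ".manifest.json")
    role, regime = "train", "full"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        role = meta.get("role", role)
        regime = meta.get("regime", regime)
    arr = np.asarray(labels, dtype=int)
    frac = float(arr.mean()) if len(arr) else 0.0
    return PairDataset(pairs, arr, role=role, regime=regime,
                       positive_fraction=frac)
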