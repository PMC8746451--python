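"""Per-protein sequence descriptors behind a uniform encoder interface.

Every encoder maps an amino-acid sequence to a fixed-dimension real vector
(or an ``L x 20`` matrix for the positional encodings).  Pair features are
formed by concatenating the two protein vectors in canonical order, which
makes every downstream model invariant to the orientation of a pair.

Letters outside the 20-letter standard alphabet (B, J, O, U, X, Z...) are
tolerated on input: they contribute zero counts to composition-style
descriptors and are dropped from the numeric property signals that the
covariance/autocorrelation/wavelet descriptors operate on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt
from Bio.Align import substitution_matrices
from scipy.fft import dct

from .io_formats import STANDARD_AMINO_ACIDS, ParseError

AA = STANDARD_AMINO_ACIDS
AA_INDEX = {a: i for i, a in enumerate(AA)}


class LengthError(ValueError):
    """Sequence too short for the requested lag/window/filter."""


# ---------------------------------------------------------------------------
# Physicochemical property tables
# ---------------------------------------------------------------------------
# Commonly used per-residue property values (hydrophobicity scale of the
# auto-covariance literature, Hopp-Woods hydrophilicity, Grantham polarity,
# side-chain volumes, polarizability, solvent-accessible surface area and a
# net-charge index).  Descriptors standardize these to zero mean / unit
# variance over the 20 amino acids before use.

RAW_PROPERTIES: dict[str, dict[str, float]] = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
        "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
        "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
        "W": 0.81, "Y": 0.26},
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
        "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
        "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
        "W": -3.4, "Y": -2.3},
    "polarity": {
        "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
        "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
        "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
        "W": 5.4, "Y": 6.2},
    "polarizability": {
        "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290, "G": 0.000,
        "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186, "M": 0.221, "N": 0.134,
        "P": 0.131, "Q": 0.180, "R": 0.291, "S": 0.062, "T": 0.108, "V": 0.140,
        "W": 0.409, "Y": 0.298},
    "charge": {
        "A": 0.007187, "C": -0.03661, "D": -0.02382, "E": 0.006802,
        "F": 0.037552, "G": 0.179052, "H": -0.01069, "I": 0.021631,
        "K": 0.017708, "L": 0.051672, "M": 0.002683, "N": 0.005392,
        "P": 0.239531, "Q": 0.049211, "R": 0.043587, "S": 0.004627,
        "T": 0.003352, "V": 0.057004, "W": 0.037977, "Y": 0.023599},
    "sasa": {
        "A": 1.181, "C": 1.461, "D": 1.587, "E": 1.862, "F": 2.228, "G": 0.881,
        "H": 2.025, "I": 1.810, "K": 2.258, "L": 1.931, "M": 2.034, "N": 1.655,
        "P": 1.468, "Q": 1.932, "R": 2.560, "S": 1.298, "T": 1.525, "V": 1.645,
        "W": 2.663, "Y": 2.368},
    "vdw_volume": {
        "A": 27.5, "C": 44.6, "D": 40.0, "E": 62.0, "F": 115.5, "G": 0.0,
        "H": 79.0, "I": 93.5, "K": 100.0, "L": 93.5, "M": 94.1, "N": 58.7,
        "P": 41.9, "Q": 80.7, "R": 105.0, "S": 29.3, "T": 51.3, "V": 71.5,
        "W": 145.5, "Y": 117.3},
}

#: Side-chain masses, the classic third property of pseudo amino acid
#: composition alongside hydrophobicity and hydrophilicity.
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0}


@dataclass
class PropertyTable:
    """Named per-residue property maps, optionally standardized."""

    properties: dict[str, dict[str, float]]
    standardized: bool = False

    def names(self) -> list[str]:
        return list(self.properties)

    def standardize(self) -> "PropertyTable":
        """Zero mean / unit (population) variance over the 20 amino acids."""
        if self.standardized:
            return self
        out = {}
        for name, table in self.properties.items():
            vals = np.array([table[a] for a in AA], dtype=float)
            mu, sd = vals.mean(), vals.std()
            if sd == 0:
                raise ValueError(f"property {name!r} is constant")
            out[name] = {a: (table[a] - mu) / sd for a in AA}
        return PropertyTable(out, standardized=True)

    def signal(self, name: str, seq: str) -> np.ndarray:
        """Property signal over the standard-letter subsequence."""
        table = self.properties[name]
        return np.array([table[c] for c in seq if c in table], dtype=float)


def default_properties() -> PropertyTable:
    """The standardized 7-property default set."""
    return PropertyTable(RAW_PROPERTIES).standardize()


def pseaac_properties() -> PropertyTable:
    """Hydrophobicity / hydrophilicity / side-chain mass, standardized."""
    return PropertyTable({
        "hydrophobicity": RAW_PROPERTIES["hydrophobicity"],
        "hydrophilicity": RAW_PROPERTIES["hydrophilicity"],
        "side_chain_mass": SIDE_CHAIN_MASS,
    }).standardize()


# ---------------------------------------------------------------------------
# Reduced alphabets
# ---------------------------------------------------------------------------

#: The 7-class conjoint-triad grouping of the 20 amino acids.
CONJOINT_CLASSES: tuple[str, ...] = (
    "AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
CONJOINT_INDEX = {a: i for i, grp in enumerate(CONJOINT_CLASSES) for a in grp}

#: Canonical 3-group partitions used by the composition/transition/
#: distribution descriptor: 7 physicochemical attributes, 3 groups each.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

#: Amino-acid groups behind the three grouped-weight binary projections:
#: neutral/non-polar, neutral/polar, acidic, basic.
EBGW_GROUPS = ("GAVLIMPFW", "QNSTYC", "DE", "HKR")


def _standard_only(seq: str) -> str:
    return "".join(c for c in seq if c in AA_INDEX)


def _conjoint_indices(seq: str) -> list[int]:
    return [CONJOINT_INDEX[c] for c in seq if c in CONJOINT_INDEX]


@dataclass
class EncoderConfig:
    """Free parameters of the descriptor family, with library defaults."""

    max_lag: int = 30            # auto covariance / autocorrelation g
    pseaac_lambda: int = 15
    pseaac_weight: float = 0.05
    qso_maxlag: int = 30
    qso_weight: float = 0.1
    ebgw_groups: int = 10
    wavelet: str = "db2"
    dwt_level: int = 3
    cgr_resolution: int = 8
    onehot_length: int = 512
    skipgram_dim: int = 20
    skipgram_window: int = 5
    skipgram_epochs: int = 3
    skipgram_seed: int = 0
    ct_max_gap: int = 3          # weighted skip-sequential conjoint triad

    def __post_init__(self) -> None:
        if self.pseaac_lambda < 1:
            raise ValueError("pseaac lambda must be >= 1")
        if self.pseaac_weight <= 0 or self.qso_weight <= 0:
            raise ValueError("weights must be positive")


# ---------------------------------------------------------------------------
# Composition-family encoders
# ---------------------------------------------------------------------------

def encode_composition(seq: str, k: int = 1,
                       alphabet: str = "standard") -> np.ndarray:
    """k-mer composition over the 20-letter or 7-class alphabet.

    k=1 standard gives amino-acid composition (20 frequencies summing to 1),
    k=2 standard the 400-dim dipeptide composition, and k=3 conjoint the
    343-dim conjoint triad with per-protein (f - min) / max normalization.
    """
    if alphabet == "standard":
        idx = [AA_INDEX[c] for c in seq if c in AA_INDEX]
        n_sym = 20
    elif alphabet in ("conjoint", "7class"):
        idx = _conjoint_indices(seq)
        n_sym = 7
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    counts = np.zeros(n_sym ** k)
    for i in range(len(idx) - k + 1):
        code = 0
        for j in range(k):
            code = code * n_sym + idx[i + j]
        counts[code] += 1
    total = counts.sum()
    if total == 0:
        return counts
    if alphabet != "standard" and k == 3:
        # conjoint triad normalization
        return (counts - counts.min()) / counts.max()
    return counts / total


def encode_conjoint_triad(seq: str) -> np.ndarray:
    """343-dim conjoint triad (3-mers over the 7-class alphabet)."""
    return encode_composition(seq, k=3, alphabet="conjoint")


def encode_ws_conjoint_triad(seq: str, max_gap: int = 3) -> np.ndarray:
    """Conjoint-triad variant over equally spaced non-adjacent triples.

    Positions (i, i+g, i+2g) for gaps g = 1..max_gap contribute weight 1/g to
    their class-triad bin; gap 1 recovers the plain conjoint triad counts.
    Normalized per protein as (f - min) / max.
    """
    idx = _conjoint_indices(seq)
    counts = np.zeros(343)
    for g in range(1, max_gap + 1):
        w = 1.0 / g
        for i in range(len(idx) - 2 * g):
            code = idx[i] * 49 + idx[i + g] * 7 + idx[i + 2 * g]
            counts[code] += w
    if counts.max() == 0:
        return counts
    return (counts - counts.min()) / counts.max()


# ---------------------------------------------------------------------------
# Property-signal encoders
# ---------------------------------------------------------------------------

def encode_auto_covariance(seq: str, props: PropertyTable | None = None,
                           g: int = 30) -> np.ndarray:
    """Auto covariance of standardized property signals at lags 1..g.

    AC(j, lag) = (1/(L-lag)) * sum_i (P_j(i) - mean_j)(P_j(i+lag) - mean_j)
    with the mean taken over the sequence.
    """
    props = (props or default_properties()).standardize()
    clean = _standard_only(seq)
    L = len(clean)
    if g >= L:
        raise LengthError(f"lag {g} >= usable sequence length {L}")
    out = np.empty(len(props.names()) * g)
    pos = 0
    for name in props.names():
        x = props.signal(name, clean)
        xc = x - x.mean()
        for lag in range(1, g + 1):
            out[pos] = float(xc[:-lag] @ xc[lag:]) / (L - lag)
            pos += 1
    return out


def encode_autocorrelation(seq: str, kind: str = "moran",
                           props: PropertyTable | None = None,
                           g: int = 30) -> np.ndarray:
    """Moran / Geary / normalized Moreau-Broto lag statistics, lags 1..g.

    Zero sequence variance (homopolymers) makes Moran and Geary 0 by the
    declared degenerate-case rule.
    """
    if kind not in ("moran", "geary", "moreau_broto_normalized"):
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    props = (props or default_properties()).standardize()
    clean = _standard_only(seq)
    L = len(clean)
    if g >= L:
        raise LengthError(f"lag {g} >= usable sequence length {L}")
    out = np.empty(len(props.names()) * g)
    pos = 0
    for name in props.names():
        x = props.signal(name, clean)
        xc = x - x.mean()
        var_pop = float(xc @ xc) / L
        var_samp = float(xc @ xc) / (L - 1) if L > 1 else 0.0
        # constant signals: rounding can leave a ~1e-30 residual variance
        if var_pop < 1e-12:
            var_pop = var_samp = 0.0
        for lag in range(1, g + 1):
            if kind == "moran":
                if var_pop == 0:
                    out[pos] = 0.0
                else:
                    num = float(xc[:-lag] @ xc[lag:]) / (L - lag)
                    out[pos] = num / var_pop
            elif kind == "geary":
                if var_samp == 0:
                    out[pos] = 0.0
                else:
                    diff = x[:-lag] - x[lag:]
                    num = float(diff @ diff) / (2.0 * (L - lag))
                    out[pos] = num / var_samp
            else:  # moreau_broto_normalized
                out[pos] = float(x[:-lag] @ x[lag:]) / (L - lag)
            pos += 1
    return out


def _grouped_ctd(group_idx: list[int], n_groups: int) -> np.ndarray:
    """Composition / transition / distribution over a grouped sequence.

    Returns ``n_groups`` composition fractions, ``C(n_groups, 2)`` unordered
    transition fractions, and 5 distribution positions (first, 25%, 50%, 75%,
    last occurrence, sequence-relative) per group.  Absent groups contribute
    zeros.
    """
    n = len(group_idx)
    n_trans = n_groups * (n_groups - 1) // 2
    out = np.zeros(n_groups + n_trans + 5 * n_groups)
    if n == 0:
        return out
    arr = np.asarray(group_idx)
    for gidx in range(n_groups):
        out[gidx] = float(np.sum(arr == gidx)) / n
    if n > 1:
        t = 0
        pair_pos = {}
        for i in range(n_groups):
            for j in range(i + 1, n_groups):
                pair_pos[(i, j)] = t
                t += 1
        a, b = arr[:-1], arr[1:]
        for x, y in zip(a, b):
            if x != y:
                key = (min(x, y), max(x, y))
                out[n_groups + pair_pos[key]] += 1
        out[n_groups:n_groups + n_trans] /= (n - 1)
    base = n_groups + n_trans
    for gidx in range(n_groups):
        positions = np.flatnonzero(arr == gidx) + 1  # 1-based
        if len(positions) == 0:
            continue
        m = len(positions)
        for qi, q in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            k = 1 if q == 0.0 else int(math.ceil(q * m))
            out[base + 5 * gidx + qi] = positions[k - 1] / n
    return out


def encode_ctd(seq: str) -> np.ndarray:
    """Composition-transition-distribution descriptor.

    7 physicochemical attributes x (3 composition + 3 transition + 15
    distribution) = 147 values.
    """
    clean = _standard_only(seq)
    parts = []
    for name, groups in CTD_GROUPS.items():
        lookup = {a: gi for gi, grp in enumerate(groups) for a in grp}
        idx = [lookup[c] for c in clean]
        parts.append(_grouped_ctd(idx, 3))
    return np.concatenate(parts)


def encode_pseaac(seq: str, lam: int = 15, w: float = 0.05,
                  props: PropertyTable | None = None) -> np.ndarray:
    """Type-1 pseudo amino acid composition (20 + lambda components).

    theta_k is the mean over i of the average squared difference of
    standardized property values between residues i and i+k; the full vector
    is normalized to sum to 1.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if w <= 0:
        raise ValueError("weight must be positive")
    props = (props or pseaac_properties()).standardize()
    clean = _standard_only(seq)
    L = len(clean)
    if L <= lam:
        raise LengthError(f"lambda {lam} >= usable sequence length {L}")
    freqs = encode_composition(clean, k=1)
    signals = np.stack([props.signal(name, clean) for name in props.names()])
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        diffs = signals[:, :-k] - signals[:, k:]
        theta[k - 1] = float(np.mean(np.mean(diffs ** 2, axis=0)))
    denom = freqs.sum() + w * theta.sum()
    return np.concatenate([freqs, w * theta]) / denom


def default_distance_matrix(props: PropertyTable | None = None) -> np.ndarray:
    """20x20 residue distance: Euclidean distance between standardized
    physicochemical property vectors."""
    props = (props or default_properties()).standardize()
    vecs = np.stack([[props.properties[name][a] for name in props.names()]
                     for a in AA])
    diff = vecs[:, None, :] - vecs[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def sequence_order_coupling(seq: str, distance_matrix: np.ndarray | None = None,
                            maxlag: int = 30) -> np.ndarray:
    """tau_d = sum_i d(R_i, R_{i+d})^2 for d = 1..maxlag."""
    dm = default_distance_matrix() if distance_matrix is None else distance_matrix
    idx = np.array([AA_INDEX[c] for c in seq if c in AA_INDEX])
    L = len(idx)
    if maxlag >= L:
        raise LengthError(f"maxlag {maxlag} >= usable sequence length {L}")
    tau = np.empty(maxlag)
    for d in range(1, maxlag + 1):
        tau[d - 1] = float(np.sum(dm[idx[:-d], idx[d:]] ** 2))
    return tau


def encode_qso(seq: str, distance_matrix: np.ndarray | None = None,
               maxlag: int = 30, w: float = 0.1) -> np.ndarray:
    """Quasi-sequence-order descriptor (20 + maxlag components, sums to 1)."""
    tau = sequence_order_coupling(seq, distance_matrix, maxlag)
    freqs = encode_composition(seq, k=1)
    denom = freqs.sum() + w * tau.sum()
    if denom == 0:
        return np.zeros(20 + maxlag)
    return np.concatenate([freqs, w * tau]) / denom


def encode_ebgw(seq: str, n_groups: int = 10) -> np.ndarray:
    """Encoding based on grouped weight: 3 binary projections x n_groups.

    The three projections dichotomize the 4 canonical charge/polarity groups;
    weight j is the fraction of ones within the first floor(j*L/n) positions.
    """
    clean = _standard_only(seq)
    L = len(clean)
    g1, g2, g3, g4 = EBGW_GROUPS
    projections = (set(g1) | set(g2), set(g1) | set(g3), set(g1) | set(g4))
    out = np.zeros(3 * n_groups)
    if L == 0:
        return out
    for pi, members in enumerate(projections):
        bits = np.array([1.0 if c in members else 0.0 for c in clean])
        csum = np.cumsum(bits)
        for j in range(1, n_groups + 1):
            plen = (j * L) // n_groups
            if plen >= 1:
                out[pi * n_groups + (j - 1)] = csum[plen - 1] / plen
    return out


# ---------------------------------------------------------------------------
# Local descriptors (region-wise grouped CTD over the 7-class alphabet)
# ---------------------------------------------------------------------------

def _ld_regions(n: int, scheme: str) -> list[tuple[int, ...]]:
    """Region index tuples (start, stop) pairs concatenated, over length n."""
    q = [0, n // 4, n // 2, (3 * n) // 4, n]
    quarters = [(q[i], q[i + 1]) for i in range(4)]
    if scheme == "LD10":
        regions = [
            quarters[0], quarters[1], quarters[2], quarters[3],
            (q[0], q[2]), (q[1], q[3]), (q[2], q[4]),       # adjacent pairs
            (q[0], q[3]), (q[1], q[4]),                     # three-quarters
            (n // 4, (3 * n) // 4),                          # central half
        ]
        return [r for r in regions]
    if scheme == "MLD":
        regions = []
        for depth in range(4):          # 1 + 2 + 4 + 8 = 15 regions
            parts = 2 ** depth
            for i in range(parts):
                regions.append(((i * n) // parts, ((i + 1) * n) // parts))
        return regions
    if scheme == "MCD":
        # all 15 non-empty subsets of the 4 quarters, in index order
        regions = []
        for mask in range(1, 16):
            segs = tuple(quarters[i] for i in range(4) if mask & (1 << i))
            regions.append(segs)
        return regions
    raise ValueError(f"unknown local-descriptor scheme {scheme!r}")


def encode_local_descriptor(seq: str, scheme: str = "LD10") -> np.ndarray:
    """Region-wise composition/transition/distribution over the 7-class
    alphabet.  Each region emits 7 C + 21 T + 35 D = 63 values; LD10 uses 10
    regions (630 dims), MLD and MCD use 15 (945 dims)."""
    idx = _conjoint_indices(seq)
    n = len(idx)
    parts = []
    for region in _ld_regions(n, scheme):
        if isinstance(region[0], tuple):  # MCD: multiple segments
            seg = [x for (s, e) in region for x in idx[s:e]]
        else:
            s, e = region
            seg = idx[s:e]
        parts.append(_grouped_ctd(seg, 7))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Multivariate mutual information
# ---------------------------------------------------------------------------

def _multiset_pairs(n: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(n) for b in range(a, n)]


def _multiset_triples(n: int) -> list[tuple[int, int, int]]:
    return [(a, b, c) for a in range(n) for b in range(a, n)
            for c in range(b, n)]


def encode_mmi(seq: str) -> np.ndarray:
    """Mutual-information statistics of 7-class 2-mer and 3-mer frequencies.

    Features: 7 class frequencies, 28 pairwise mutual-information terms
    f2 * ln(f2 / E2) over adjacent unordered 2-mers, and 84 third-order terms
    f3 * ln(f3 / E3) over adjacent unordered 3-mers, where E is the
    independence expectation with multiset multiplicity.  The 0*log(0) = 0
    convention keeps homopolymer terms exactly zero.  Dimension 119.
    """
    idx = _conjoint_indices(seq)
    n = len(idx)
    uni = np.zeros(7)
    for c in idx:
        uni[c] += 1
    if n:
        uni /= n
    pairs = _multiset_pairs(7)
    triples = _multiset_triples(7)
    pair_pos = {p: i for i, p in enumerate(pairs)}
    triple_pos = {t: i for i, t in enumerate(triples)}
    f2 = np.zeros(len(pairs))
    for i in range(n - 1):
        a, b = sorted((idx[i], idx[i + 1]))
        f2[pair_pos[(a, b)]] += 1
    if n > 1:
        f2 /= (n - 1)
    f3 = np.zeros(len(triples))
    for i in range(n - 2):
        a, b, c = sorted((idx[i], idx[i + 1], idx[i + 2]))
        f3[triple_pos[(a, b, c)]] += 1
    if n > 2:
        f3 /= (n - 2)

    mi2 = np.zeros(len(pairs))
    for i, (a, b) in enumerate(pairs):
        if f2[i] > 0:
            expect = (2.0 if a != b else 1.0) * uni[a] * uni[b]
            mi2[i] = f2[i] * math.log(f2[i] / expect)
    mi3 = np.zeros(len(triples))
    for i, (a, b, c) in enumerate(triples):
        if f3[i] > 0:
            # multiplicity of the multiset {a,b,c} among ordered triples
            if a == b == c:
                mult = 1.0
            elif a == b or b == c or a == c:
                mult = 3.0
            else:
                mult = 6.0
            expect = mult * uni[a] * uni[b] * uni[c]
            mi3[i] = f3[i] * math.log(f3[i] / expect)
    return np.concatenate([uni, mi2, mi3])


# ---------------------------------------------------------------------------
# Chaos game representation
# ---------------------------------------------------------------------------

#: Residue vertices equally spaced on the unit circle.
CGR_VERTICES = np.stack([(math.cos(2 * math.pi * k / 20),
                          math.sin(2 * math.pi * k / 20)) for k in range(20)])


def cgr_trajectory(seq: str) -> np.ndarray:
    """Chaos-game point cloud: x_n = (x_{n-1} + V(R_n)) / 2 from the origin."""
    idx = [AA_INDEX[c] for c in seq if c in AA_INDEX]
    pts = np.empty((len(idx), 2))
    x = np.zeros(2)
    for i, k in enumerate(idx):
        x = (x + CGR_VERTICES[k]) / 2.0
        pts[i] = x
    return pts


def encode_cgr(seq: str, grid_resolution: int = 8) -> np.ndarray:
    """Normalized cell occupancy of the chaos-game point cloud on a
    grid_resolution^2 grid over [-1, 1]^2 (sums to 1)."""
    pts = cgr_trajectory(seq)
    res = grid_resolution
    out = np.zeros(res * res)
    if len(pts) == 0:
        return out
    cells = np.clip(((pts + 1.0) / 2.0 * res).astype(int), 0, res - 1)
    for cx, cy in cells:
        out[cx * res + cy] += 1
    return out / len(pts)


# ---------------------------------------------------------------------------
# Discrete wavelet transform of property signals
# ---------------------------------------------------------------------------

def encode_dwt_physicochemical(seq: str, props: PropertyTable | None = None,
                               wavelet: str = "db2",
                               level: int = 3) -> np.ndarray:
    """Wavelet-decomposition summary of each property signal.

    Per property the standardized signal is decomposed to ``level`` levels;
    features are {max, min, mean, sd} of the approximation and each detail
    band: |props| x (level + 1) x 4 values.
    """
    props = (props or default_properties()).standardize()
    clean = _standard_only(seq)
    wav = pywt.Wavelet(wavelet)
    min_len = wav.dec_len * 2 ** (level - 1)
    if len(clean) < wav.dec_len:
        raise LengthError(
            f"sequence length {len(clean)} below filter support {wav.dec_len}")
    feats = []
    for name in props.names():
        x = props.signal(name, clean)
        coeffs = pywt.wavedec(x, wav, level=level)
        for band in coeffs:
            feats.extend((float(band.max()), float(band.min()),
                          float(band.mean()), float(band.std())))
    return np.asarray(feats)


# ---------------------------------------------------------------------------
# Positional encodings: one-hot, BLOSUM62, PSSM
# ---------------------------------------------------------------------------

def encode_onehot(seq: str, fixed_length: int, flatten: bool = False) -> np.ndarray:
    """L x 20 indicator rows, truncated/padded to ``fixed_length``; pad rows
    (and rows for non-standard letters) are all-zero."""
    mat = np.zeros((fixed_length, 20))
    for i, c in enumerate(seq[:fixed_length]):
        j = AA_INDEX.get(c)
        if j is not None:
            mat[i, j] = 1.0
    return mat.ravel() if flatten else mat


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 restricted to the 20 standard residues, row per residue.
BLOSUM62_ROWS: dict[str, np.ndarray] = {
    a: np.array([float(_BLOSUM62[a, b]) for b in AA]) for a in AA}


def encode_blosum62(seq: str, fixed_length: int | None = None,
                    flatten: bool = False) -> np.ndarray:
    """Each residue replaced by its 20-value BLOSUM62 substitution row;
    unknown letters map to all-zero rows."""
    L = fixed_length if fixed_length is not None else len(seq)
    mat = np.zeros((L, 20))
    for i, c in enumerate(seq[:L]):
        row = BLOSUM62_ROWS.get(c)
        if row is not None:
            mat[i] = row
    return mat.ravel() if flatten else mat


def read_pssm(path: str | Path) -> np.ndarray:
    """Read a PSI-BLAST ASCII position-specific scoring matrix (L x 20).

    Rows whose first token is a position index contribute their first 20
    numeric columns (the log-odds block).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if len(toks) < 22 or not toks[0].isdigit():
                continue
            if toks[1] not in AA_INDEX and toks[1] != "X":
                continue
            try:
                rows.append([float(t) for t in toks[2:22]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad PSSM row") from exc
    if not rows:
        raise ParseError(f"{path}: no PSSM rows found")
    return np.asarray(rows)


def pssm_or_blosum62(seq: str, pssm_path: str | Path | None) -> np.ndarray:
    """Per-residue scoring matrix: the protein's PSSM when available, else
    the BLOSUM62 fallback encoding."""
    if pssm_path is not None and Path(pssm_path).exists():
        return read_pssm(pssm_path)
    return encode_blosum62(seq)


def pssm_dpc(matrix: np.ndarray) -> np.ndarray:
    """400-dim PSSM bi-gram/dipeptide pooling:
    B(i, j) = (1/(L-1)) * sum_k M[k, i] * M[k+1, j]."""
    m = np.asarray(matrix, dtype=float)
    if len(m) < 2:
        raise LengthError("PSSM bigram needs at least 2 rows")
    return (m[:-1].T @ m[1:]).ravel() / (len(m) - 1)


def pssm_dct(matrix: np.ndarray, n_coeffs: int = 20) -> np.ndarray:
    """Discrete-cosine-transform pooling along the sequence axis: the first
    ``n_coeffs`` DCT-II coefficient rows, flattened (n_coeffs x 20)."""
    m = np.asarray(matrix, dtype=float)
    coeffs = dct(m, type=2, axis=0, norm="ortho")
    out = np.zeros((n_coeffs, m.shape[1]))
    take = min(n_coeffs, coeffs.shape[0])
    out[:take] = coeffs[:take]
    return out.ravel()


# ---------------------------------------------------------------------------
# Skip-gram residue embeddings
# ---------------------------------------------------------------------------

def train_skipgram(proteome, dim: int = 20, window: int = 5,
                   epochs: int = 3, negative: int = 5, lr: float = 0.025,
                   seed: int = 0) -> dict[str, np.ndarray]:
    """Train residue-level skip-gram embeddings with negative sampling.

    The corpus is every sequence in the proteome (standard letters only);
    tokens are single residues.  Deterministic under a fixed seed.  Returns a
    residue -> vector table.
    """
    sequences = [_standard_only(rec.sequence)
                 for rec in sorted(proteome, key=lambda r: r.protein_id)]
    sequences = [s for s in sequences if len(s) >= 2]
    rng = np.random.default_rng(seed)
    counts = np.zeros(20)
    for s in sequences:
        for c in s:
            counts[AA_INDEX[c]] += 1
    noise = counts ** 0.75
    if noise.sum() == 0:
        noise = np.ones(20)
    noise /= noise.sum()
    W = (rng.random((20, dim)) - 0.5) / dim   # center vectors
    C = np.zeros((20, dim))                   # context vectors
    for epoch in range(epochs):
        alpha = lr * (1.0 - epoch / max(epochs, 1)) + 1e-4
        for s in sequences:
            idx = [AA_INDEX[c] for c in s]
            for i, wi in enumerate(idx):
                lo, hi = max(0, i - window), min(len(idx), i + window + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    targets = [idx[j]] + list(
                        rng.choice(20, size=negative, p=noise))
                    labels = [1.0] + [0.0] * negative
                    v = W[wi]
                    grad_v = np.zeros(dim)
                    for t, y in zip(targets, labels):
                        z = 1.0 / (1.0 + math.exp(-float(v @ C[t])))
                        g = alpha * (y - z)
                        grad_v += g * C[t]
                        C[t] += g * v
                    W[wi] += grad_v
    return {a: W[AA_INDEX[a]].copy() for a in AA}


def encode_skipgram(seq: str, table: dict[str, np.ndarray],
                    pooling: str = "mean") -> np.ndarray:
    """Pool per-residue embeddings into a protein vector."""
    vecs = [table[c] for c in seq if c in table]
    dim = len(next(iter(table.values())))
    if not vecs:
        return np.zeros(dim)
    arr = np.stack(vecs)
    if pooling == "mean":
        return arr.mean(axis=0)
    if pooling == "sum":
        return arr.sum(axis=0)
    if pooling == "max":
        return arr.max(axis=0)
    raise ValueError(f"unknown pooling {pooling!r}")


# ---------------------------------------------------------------------------
# Encoder registry, pair features and normalization
# ---------------------------------------------------------------------------

def build_encoder_registry(config: EncoderConfig | None = None,
                           skipgram_table: dict[str, np.ndarray] | None = None,
                           ) -> dict:
    """Name -> callable(sequence) -> vector, for CLI/config addressing."""
    cfg = config or EncoderConfig()
    reg = {
        "aac": lambda s: encode_composition(s, 1),
        "dipeptide": lambda s: encode_composition(s, 2),
        "ct": encode_conjoint_triad,
        "ws_ct": lambda s: encode_ws_conjoint_triad(s, cfg.ct_max_gap),
        "ac": lambda s: encode_auto_covariance(s, g=cfg.max_lag),
        "ctd": encode_ctd,
        "moran": lambda s: encode_autocorrelation(s, "moran", g=cfg.max_lag),
        "geary": lambda s: encode_autocorrelation(s, "geary", g=cfg.max_lag),
        "moreau_broto": lambda s: encode_autocorrelation(
            s, "moreau_broto_normalized", g=cfg.max_lag),
        "pseaac": lambda s: encode_pseaac(s, cfg.pseaac_lambda, cfg.pseaac_weight),
        "qso": lambda s: encode_qso(s, maxlag=cfg.qso_maxlag, w=cfg.qso_weight),
        "sequence_order": lambda s: sequence_order_coupling(s, maxlag=cfg.qso_maxlag),
        "ebgw": lambda s: encode_ebgw(s, cfg.ebgw_groups),
        "ld10": lambda s: encode_local_descriptor(s, "LD10"),
        "mld": lambda s: encode_local_descriptor(s, "MLD"),
        "mcd": lambda s: encode_local_descriptor(s, "MCD"),
        "mmi": encode_mmi,
        "cgr": lambda s: encode_cgr(s, cfg.cgr_resolution),
        "dwt": lambda s: encode_dwt_physicochemical(
            s, wavelet=cfg.wavelet, level=cfg.dwt_level),
        "onehot": lambda s: encode_onehot(s, cfg.onehot_length, flatten=True),
        "blosum62": lambda s: encode_blosum62(
            s, fixed_length=cfg.onehot_length, flatten=True),
    }
    if skipgram_table is not None:
        reg["skipgram"] = lambda s: encode_skipgram(s, skipgram_table)
    return reg


def pair_features(encoder, record_a, record_b) -> np.ndarray:
    """Concatenate the two protein vectors in canonical order
    (lexicographically smaller protein_id first)."""
    first, second = ((record_a, record_b)
                     if record_a.protein_id <= record_b.protein_id
                     else (record_b, record_a))
    va = np.asarray(encoder(first.sequence), dtype=float).ravel()
    vb = np.asarray(encoder(second.sequence), dtype=float).ravel()
    return np.concatenate([va, vb])


def encode_pairs(encoder, proteome, pairs) -> np.ndarray:
    """Feature matrix (one row per pair), caching per-protein vectors."""
    cache: dict[str, np.ndarray] = {}

    def vec(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = np.asarray(
                encoder(proteome.sequence(pid)), dtype=float).ravel()
        return cache[pid]

    rows = []
    for a, b in pairs:
        x, y = (a, b) if a <= b else (b, a)
        rows.append(np.concatenate([vec(x), vec(y)]))
    return np.stack(rows) if rows else np.zeros((0, 0))


@dataclass
class FeatureMatrix:
    """Per-pair feature rows with encoder provenance and normalization state."""

    values: np.ndarray
    encoder: str = ""
    normalization: str = "none"           # none | minmax01 | symmetric11
    fit_min: np.ndarray | None = None
    fit_max: np.ndarray | None = None
    fit_split: str = ""

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Apply the fitted normalization to new rows, clipping to range."""
        if self.normalization == "none":
            return np.asarray(values, dtype=float)
        lo, hi = self.fit_min, self.fit_max
        span = np.where(hi > lo, hi - lo, 1.0)
        scaled = (np.asarray(values, dtype=float) - lo) / span
        scaled = np.where(hi > lo, scaled, 0.0)
        scaled = np.clip(scaled, 0.0, 1.0)
        if self.normalization == "symmetric11":
            return 2.0 * scaled - 1.0
        return scaled


def normalize(values: np.ndarray, mode: str = "minmax01",
              fit_rows: np.ndarray | None = None,
              fit_split: str = "train", encoder: str = "") -> FeatureMatrix:
    """Fit column-wise range normalization on the training rows only.

    ``fit_rows`` is a boolean mask (or index array) naming the training rows;
    statistics are fit there and applied everywhere, with out-of-range test
    values clipped to the fitted range.
    """
    values = np.asarray(values, dtype=float)
    if mode not in ("none", "minmax01", "symmetric11"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "none":
        return FeatureMatrix(values.copy(), encoder=encoder)
    fit = values if fit_rows is None else values[fit_rows]
    if len(fit) == 0:
        raise ValueError("no rows to fit normalization on")
    fm = FeatureMatrix(values, encoder=encoder, normalization=mode,
                       fit_min=fit.min(axis=0), fit_max=fit.max(axis=0),
                       fit_split=fit_split)
    fm.values = fm.transform(values)
    return fm
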