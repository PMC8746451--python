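"""Sequence descriptors against independently coded brute-force oracles.

The oracle implementations below are deliberately naive (dict counting,
double loops over lags, direct formula transcription) and share no code with
the library encoders they check.
"""

import itertools
import math

import numpy as np
import pytest

from conftest import random_sequences
from ppibench.io_formats import ProteinRecord, Proteome
from ppibench.sequence_features import (
    AA,
    CONJOINT_CLASSES,
    CONJOINT_INDEX,
    CTD_GROUPS,
    EBGW_GROUPS,
    EncoderConfig,
    LengthError,
    PropertyTable,
    RAW_PROPERTIES,
    build_encoder_registry,
    cgr_trajectory,
    default_distance_matrix,
    default_properties,
    encode_auto_covariance,
    encode_autocorrelation,
    encode_blosum62,
    encode_cgr,
    encode_composition,
    encode_conjoint_triad,
    encode_ctd,
    encode_dwt_physicochemical,
    encode_ebgw,
    encode_local_descriptor,
    encode_mmi,
    encode_onehot,
    encode_pseaac,
    encode_qso,
    encode_skipgram,
    encode_ws_conjoint_triad,
    normalize,
    pair_features,
    pseaac_properties,
    pssm_dct,
    pssm_dpc,
    pssm_or_blosum62,
    read_pssm,
    sequence_order_coupling,
    train_skipgram,
)

ORACLE_SEQS = random_sequences(100, 31, 200, seed=123)
G = 12  # lag used in the oracle comparisons (well below min length 31)


# ---------------------------------------------------------------------------
# Oracles (independent naive implementations)
# ---------------------------------------------------------------------------

def oracle_kmer_freq(seq, k, alphabet_index, n_sym):
    counts = {}
    valid = [c for c in seq if c in alphabet_index]
    for i in range(len(valid) - k + 1):
        key = tuple(alphabet_index[c] for c in valid[i:i + k])
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    vec = []
    for key in itertools.product(range(n_sym), repeat=k):
        vec.append(counts.get(key, 0) / total if total else 0.0)
    return np.array(vec)


def oracle_std_props():
    out = {}
    for name, table in RAW_PROPERTIES.items():
        vals = [table[a] for a in AA]
        mu = sum(vals) / 20.0
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / 20.0)
        out[name] = {a: (table[a] - mu) / sd for a in AA}
    return out


def oracle_auto_covariance(seq, g):
    props = oracle_std_props()
    out = []
    for name in RAW_PROPERTIES:
        x = [props[name][c] for c in seq]
        L = len(x)
        mean = sum(x) / L
        for lag in range(1, g + 1):
            s = 0.0
            for i in range(L - lag):
                s += (x[i] - mean) * (x[i + lag] - mean)
            out.append(s / (L - lag))
    return np.array(out)


def oracle_autocorrelation(seq, kind, g):
    props = oracle_std_props()
    out = []
    for name in RAW_PROPERTIES:
        x = [props[name][c] for c in seq]
        L = len(x)
        mean = sum(x) / L
        var_pop = sum((v - mean) ** 2 for v in x) / L
        var_samp = sum((v - mean) ** 2 for v in x) / (L - 1)
        for lag in range(1, g + 1):
            if kind == "moran":
                num = sum((x[i] - mean) * (x[i + lag] - mean)
                          for i in range(L - lag)) / (L - lag)
                out.append(num / var_pop if var_pop else 0.0)
            elif kind == "geary":
                num = sum((x[i] - x[i + lag]) ** 2
                          for i in range(L - lag)) / (2 * (L - lag))
                out.append(num / var_samp if var_samp else 0.0)
            else:
                out.append(sum(x[i] * x[i + lag]
                               for i in range(L - lag)) / (L - lag))
    return np.array(out)


def oracle_ctd(seq):
    out = []
    for name, groups in CTD_GROUPS.items():
        gidx = []
        for c in seq:
            for gi, grp in enumerate(groups):
                if c in grp:
                    gidx.append(gi)
                    break
        n = len(gidx)
        for gi in range(3):
            out.append(gidx.count(gi) / n)
        trans = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for i in range(n - 1):
            a, b = gidx[i], gidx[i + 1]
            if a != b:
                trans[(min(a, b), max(a, b))] += 1
        for key in ((0, 1), (0, 2), (1, 2)):
            out.append(trans[key] / (n - 1))
        for gi in range(3):
            positions = [i + 1 for i, v in enumerate(gidx) if v == gi]
            if not positions:
                out.extend([0.0] * 5)
                continue
            m = len(positions)
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                k = 1 if q == 0 else math.ceil(q * m)
                out.append(positions[k - 1] / n)
    return np.array(out)


def oracle_pseaac(seq, lam, w):
    tables = {}
    for name, table in {"hydrophobicity": RAW_PROPERTIES["hydrophobicity"],
                        "hydrophilicity": RAW_PROPERTIES["hydrophilicity"],
                        "side_chain_mass": {
                            "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0,
                            "F": 91.0, "G": 1.0, "H": 82.0, "I": 57.0,
                            "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
                            "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0,
                            "T": 45.0, "V": 43.0, "W": 130.0,
                            "Y": 107.0}}.items():
        vals = [table[a] for a in AA]
        mu = sum(vals) / 20.0
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / 20.0)
        tables[name] = {a: (table[a] - mu) / sd for a in AA}

    def theta_pair(a, b):
        return sum((tables[n][b] - tables[n][a]) ** 2
                   for n in tables) / len(tables)

    L = len(seq)
    freqs = [seq.count(a) / L for a in AA]
    thetas = []
    for k in range(1, lam + 1):
        thetas.append(sum(theta_pair(seq[i], seq[i + k])
                          for i in range(L - k)) / (L - k))
    denom = sum(freqs) + w * sum(thetas)
    return np.array(freqs + [w * t for t in thetas]) / denom


def oracle_qso(seq, maxlag, w):
    dm = default_distance_matrix()  # the declared input distance matrix
    aa_index = {a: i for i, a in enumerate(AA)}
    L = len(seq)
    taus = []
    for d in range(1, maxlag + 1):
        taus.append(sum(dm[aa_index[seq[i]], aa_index[seq[i + d]]] ** 2
                        for i in range(L - d)))
    freqs = [seq.count(a) / L for a in AA]
    denom = sum(freqs) + w * sum(taus)
    return np.array(freqs + [w * t for t in taus]) / denom


def oracle_ebgw(seq, n_groups):
    g1, g2, g3, g4 = EBGW_GROUPS
    projections = [set(g1) | set(g2), set(g1) | set(g3), set(g1) | set(g4)]
    L = len(seq)
    out = []
    for members in projections:
        bits = [1 if c in members else 0 for c in seq]
        for j in range(1, n_groups + 1):
            plen = (j * L) // n_groups
            out.append(sum(bits[:plen]) / plen if plen else 0.0)
    return np.array(out)


def oracle_mmi(seq):
    idx = [CONJOINT_INDEX[c] for c in seq]
    n = len(idx)
    uni = [idx.count(c) / n for c in range(7)]
    f2, f3 = {}, {}
    for i in range(n - 1):
        key = tuple(sorted(idx[i:i + 2]))
        f2[key] = f2.get(key, 0) + 1
    for i in range(n - 2):
        key = tuple(sorted(idx[i:i + 3]))
        f3[key] = f3.get(key, 0) + 1
    out = list(uni)
    for a in range(7):
        for b in range(a, 7):
            f = f2.get((a, b), 0) / (n - 1)
            if f == 0:
                out.append(0.0)
            else:
                e = (2 if a != b else 1) * uni[a] * uni[b]
                out.append(f * math.log(f / e))
    for a in range(7):
        for b in range(a, 7):
            for c in range(b, 7):
                f = f3.get((a, b, c), 0) / (n - 2)
                if f == 0:
                    out.append(0.0)
                    continue
                distinct = len({a, b, c})
                mult = {1: 1, 2: 3, 3: 6}[distinct]
                e = mult * uni[a] * uni[b] * uni[c]
                out.append(f * math.log(f / e))
    return np.array(out)


# ---------------------------------------------------------------------------
# Oracle agreement on random sequences
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("encoder,oracle", [
    (lambda s: encode_composition(s, 1),
     lambda s: oracle_kmer_freq(s, 1, {a: i for i, a in enumerate(AA)}, 20)),
    (lambda s: encode_composition(s, 2),
     lambda s: oracle_kmer_freq(s, 2, {a: i for i, a in enumerate(AA)}, 20)),
    (lambda s: encode_auto_covariance(s, g=G),
     lambda s: oracle_auto_covariance(s, G)),
    (encode_ctd, oracle_ctd),
    (lambda s: encode_autocorrelation(s, "moran", g=G),
     lambda s: oracle_autocorrelation(s, "moran", G)),
    (lambda s: encode_autocorrelation(s, "geary", g=G),
     lambda s: oracle_autocorrelation(s, "geary", G)),
    (lambda s: encode_autocorrelation(s, "moreau_broto_normalized", g=G),
     lambda s: oracle_autocorrelation(s, "mb", G)),
    (lambda s: encode_pseaac(s, lam=5, w=0.05),
     lambda s: oracle_pseaac(s, 5, 0.05)),
    (lambda s: encode_qso(s, maxlag=G, w=0.1),
     lambda s: oracle_qso(s, G, 0.1)),
    (lambda s: encode_ebgw(s, 10), lambda s: oracle_ebgw(s, 10)),
    (encode_mmi, oracle_mmi),
], ids=["aac", "dipeptide", "auto_covariance", "ctd", "moran", "geary",
        "moreau_broto", "pseaac", "qso", "ebgw", "mmi"])
def test_encoder_matches_bruteforce_oracle(encoder, oracle):
    for seq in ORACLE_SEQS:
        np.testing.assert_allclose(encoder(seq), oracle(seq), atol=1e-8)


def test_conjoint_triad_matches_oracle():
    for seq in ORACLE_SEQS:
        counts = {}
        idx = [CONJOINT_INDEX[c] for c in seq]
        for i in range(len(idx) - 2):
            counts[tuple(idx[i:i + 3])] = counts.get(tuple(idx[i:i + 3]), 0) + 1
        raw = np.array([counts.get(key, 0) for key in
                        itertools.product(range(7), repeat=3)], dtype=float)
        expected = (raw - raw.min()) / raw.max()
        np.testing.assert_allclose(encode_conjoint_triad(seq), expected,
                                   atol=1e-8)


# ---------------------------------------------------------------------------
# Worked examples and degeneracies
# ---------------------------------------------------------------------------

class TestCompositionExamples:
    def test_aac_homopolymer(self):
        vec = encode_composition("A" * 40, 1)
        assert vec[AA.index("A")] == 1.0 and vec.sum() == 1.0

    def test_dipeptide_acac(self):
        vec = encode_composition("ACAC", 2)
        assert vec[AA.index("A") * 20 + AA.index("C")] == pytest.approx(2 / 3)
        assert vec[AA.index("C") * 20 + AA.index("A")] == pytest.approx(1 / 3)
        assert vec.sum() == pytest.approx(1.0)

    def test_conjoint_triad_homopolymer(self):
        vec = encode_conjoint_triad("AAAAA")  # A is in class 0
        assert vec[0] == 1.0
        assert np.count_nonzero(vec) == 1

    def test_nonstandard_letters_contribute_zero(self):
        assert np.allclose(encode_composition("AXAXA", 1),
                           encode_composition("AAA", 1))


class TestAutoCovariance:
    def test_homopolymer_is_zero(self):
        assert np.allclose(encode_auto_covariance("W" * 50, g=10), 0.0)

    def test_lag_at_least_length_errors(self):
        with pytest.raises(LengthError):
            encode_auto_covariance("ACDEF" * 7, g=35)


class TestCTDExamples:
    def test_homopolymer_transitions_zero(self):
        vec = encode_ctd("A" * 40)
        # transition block of each property = indices 3..5 of each 21-slice
        for p in range(7):
            assert np.allclose(vec[21 * p + 3: 21 * p + 6], 0.0)

    def test_homopolymer_distribution_positions(self):
        L = 40
        vec = encode_ctd("A" * L)
        expected = np.array([1 / L, math.ceil(L / 4) / L, math.ceil(L / 2) / L,
                             math.ceil(3 * L / 4) / L, 1.0])
        groups = CTD_GROUPS["hydrophobicity"]
        gi = next(i for i, grp in enumerate(groups) if "A" in grp)
        block = vec[6 + 5 * gi: 6 + 5 * gi + 5]
        np.testing.assert_allclose(block, expected)
        assert vec[gi] == 1.0  # composition of A's group


class TestAutocorrelationExamples:
    def test_moran_homopolymer_zero(self):
        assert np.allclose(
            encode_autocorrelation("L" * 40, "moran", g=8), 0.0)

    def test_moreau_broto_homopolymer_is_v_squared(self):
        props = default_properties()
        v = props.properties["hydrophobicity"]["A"]
        vec = encode_autocorrelation("A" * 40, "moreau_broto_normalized", g=5)
        np.testing.assert_allclose(vec[:5], v * v)


class TestPseaacExamples:
    def test_homopolymer(self):
        vec = encode_pseaac("G" * 40, lam=5)
        assert np.allclose(vec[20:], 0.0)   # theta components
        assert vec[AA.index("G")] == pytest.approx(1.0)

    def test_sums_to_one(self):
        for seq in ORACLE_SEQS[:10]:
            assert encode_pseaac(seq, lam=8).sum() == pytest.approx(1.0)


class TestQsoExamples:
    def test_homopolymer_reduces_to_aac(self):
        vec = encode_qso("K" * 40, maxlag=5)
        np.testing.assert_allclose(vec[:20], encode_composition("K" * 40, 1))
        assert np.allclose(vec[20:], 0.0)

    def test_sums_to_one(self):
        for seq in ORACLE_SEQS[:10]:
            assert encode_qso(seq, maxlag=10).sum() == pytest.approx(1.0)

    def test_coupling_requires_length(self):
        with pytest.raises(LengthError):
            sequence_order_coupling("ACDEF", maxlag=10)


class TestEbgwExamples:
    def test_homopolymer_all_ones_projection(self):
        # G is in the neutral/non-polar group -> 1 in every projection
        assert np.allclose(encode_ebgw("G" * 40, 10), 1.0)

    def test_homopolymer_zero_projection(self):
        # D (acidic) is 0 in projections 1 and 3, 1 in projection 2
        vec = encode_ebgw("D" * 40, 10)
        assert np.allclose(vec[:10], 0.0)
        assert np.allclose(vec[10:20], 1.0)
        assert np.allclose(vec[20:], 0.0)

    def test_alternating_is_half(self):
        # G (ones) alternating with D (zeros in projection 1)
        vec = encode_ebgw("GD" * 20, 10)
        assert np.allclose(vec[:10], 0.5)


class TestLocalDescriptors:
    def test_ld10_dimension(self):
        assert encode_local_descriptor(ORACLE_SEQS[0], "LD10").shape == (630,)

    def test_mld_mcd_dimensions(self):
        assert encode_local_descriptor(ORACLE_SEQS[0], "MLD").shape == (945,)
        assert encode_local_descriptor(ORACLE_SEQS[0], "MCD").shape == (945,)

    def test_quarters_partition_length_40(self):
        from ppibench.sequence_features import _ld_regions
        regions = _ld_regions(40, "LD10")
        quarters = regions[:4]
        covered = []
        for s, e in quarters:
            covered.extend(range(s, e))
        assert covered == list(range(40))

    def test_homopolymer_transitions_zero_every_region(self):
        vec = encode_local_descriptor("A" * 48, "LD10")
        for r in range(10):
            block = vec[63 * r: 63 * (r + 1)]
            assert np.allclose(block[7:28], 0.0)  # 21 transition values


class TestMmiExamples:
    def test_homopolymer_interaction_terms_zero(self):
        vec = encode_mmi("A" * 40)
        assert np.allclose(vec[7:], 0.0)

    def test_dimension_independent_of_length(self):
        assert encode_mmi("ACD" * 15).shape == encode_mmi("W" * 200).shape \
            == (119,)


class TestCgrExamples:
    def test_aaaa_final_point_geometric_series(self):
        pts = cgr_trajectory("AAAA")
        from ppibench.sequence_features import CGR_VERTICES
        np.testing.assert_allclose(pts[-1], CGR_VERTICES[AA.index("A")]
                                   * (1 - 2 ** -4))

    def test_homopolymer_single_cell(self):
        vec = encode_cgr("C" * 60, grid_resolution=2)
        assert np.count_nonzero(vec) == 1

    def test_occupancy_sums_to_one(self):
        for seq in ORACLE_SEQS[:10]:
            assert encode_cgr(seq).sum() == pytest.approx(1.0)


class TestDwtExamples:
    def test_homopolymer_detail_features_zero(self):
        vec = encode_dwt_physicochemical("A" * 64, level=3)
        # per property: 4 bands x 4 stats; bands 1..3 are details
        per_prop = vec.reshape(7, 4, 4)
        assert np.allclose(per_prop[:, 1:, :], 0.0, atol=1e-10)

    def test_constant_signal_approx_mean_scales(self):
        import pywt
        props = default_properties()
        v = props.properties["hydrophobicity"]["A"]
        vec = encode_dwt_physicochemical("A" * 64, level=3)
        expected = pywt.wavedec(np.full(64, v), "db2", level=3)[0].mean()
        assert vec.reshape(7, 4, 4)[0, 0, 2] == pytest.approx(expected)

    def test_too_short_errors(self):
        with pytest.raises(LengthError):
            encode_dwt_physicochemical("ACD")


class TestOnehot:
    def test_rows_mark_residues(self):
        mat = encode_onehot("MA", 2)
        assert mat[0, AA.index("M")] == 1.0 and mat[1, AA.index("A")] == 1.0

    def test_padding(self):
        mat = encode_onehot("MA", 5)
        assert np.allclose(mat[2:], 0.0)

    def test_one_hot_per_nonpad_row(self):
        mat = encode_onehot("MKVACD", 6)
        assert (mat.sum(axis=1) == 1.0).all()


class TestBlosum62:
    def test_a_row_diagonal(self):
        mat = encode_blosum62("A")
        assert mat[0, AA.index("A")] == 4.0

    def test_row_width(self):
        assert encode_blosum62("MKV").shape == (3, 20)

    def test_unknown_letter_zero_row(self):
        mat = encode_blosum62("X")
        assert np.allclose(mat[0], 0.0)


PSSM_TEXT = """
Last position-specific scoring matrix computed, weighted observed percentages
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -2  -3  -1   0  -2  -3  -2   1   2  -1   6   0  -2  -1  -1  -1  -1   1
    2 K    -1   2   0  -1  -3   1   1  -1  -1  -3  -2   5  -1  -3  -1   0  -1  -3  -2  -2
    3 V     0  -3  -3  -3  -1  -2  -2  -3  -3   3   1  -2   1  -1  -2  -2   0  -3  -1   4
"""


class TestPssm:
    def test_reads_fixture_rows(self, tmp_path):
        p = tmp_path / "x.pssm"
        p.write_text(PSSM_TEXT)
        mat = read_pssm(p)
        assert mat.shape == (3, 20)
        assert mat[0, 12] == 6.0

    def test_missing_file_falls_back_to_blosum62(self):
        mat = pssm_or_blosum62("MKV", None)
        np.testing.assert_allclose(mat, encode_blosum62("MKV"))

    def test_dct_of_constant_matrix_keeps_only_dc(self):
        const = np.full((12, 20), 3.0)
        vec = pssm_dct(const, n_coeffs=5).reshape(5, 20)
        assert not np.allclose(vec[0], 0.0)
        assert np.allclose(vec[1:], 0.0, atol=1e-10)

    def test_dpc_dimension(self, tmp_path):
        p = tmp_path / "x.pssm"
        p.write_text(PSSM_TEXT)
        assert pssm_dpc(read_pssm(p)).shape == (400,)


class TestSkipGram:
    def _corpus(self, seed=0):
        return Proteome([
            ProteinRecord(f"P{i}", f"G{i}", s)
            for i, s in enumerate(random_sequences(8, 31, 40, seed=seed))])

    def test_embedding_dimension(self):
        table = train_skipgram(self._corpus(), dim=12, epochs=1)
        assert all(v.shape == (12,) for v in table.values())

    def test_seeded_determinism(self):
        prot = self._corpus()
        t1 = train_skipgram(prot, dim=8, epochs=1, seed=5)
        t2 = train_skipgram(prot, dim=8, epochs=1, seed=5)
        for a in t1:
            np.testing.assert_array_equal(t1[a], t2[a])

    def test_shared_context_beats_disjoint_context(self):
        # A and C always appear in the same context (flanked by G runs),
        # W appears only flanked by K runs; median over 20 trials.
        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        wins = []
        for trial in range(20):
            rng = np.random.default_rng(trial)
            seqs = []
            for _ in range(12):
                parts = []
                for _ in range(8):
                    if rng.random() < 0.5:
                        parts.append("GGG" + ("A" if rng.random() < 0.5
                                              else "C") + "GGG")
                    else:
                        parts.append("KKKWKKK")
                seqs.append("".join(parts))
            prot = Proteome([ProteinRecord(f"P{i}", f"G{i}", s)
                             for i, s in enumerate(seqs)])
            table = train_skipgram(prot, dim=10, window=3, epochs=2,
                                   seed=trial)
            wins.append(cos(table["A"], table["C"]) -
                        cos(table["A"], table["W"]))
        assert np.median(wins) > 0

    def test_mean_pooling(self):
        table = {"A": np.array([1.0, 0.0]), "C": np.array([0.0, 1.0])}
        np.testing.assert_allclose(encode_skipgram("AC", table), [0.5, 0.5])
        assert np.allclose(encode_skipgram("X", table), 0.0)


class TestPairFeaturesAndNormalization:
    def test_pair_orientation_invariance(self, tiny_proteome):
        enc = lambda s: encode_composition(s, 1)
        a, b = tiny_proteome["P1"], tiny_proteome["P2"]
        np.testing.assert_array_equal(pair_features(enc, a, b),
                                      pair_features(enc, b, a))

    def test_minmax_maps_train_extremes(self):
        X = np.array([[2.0], [4.0], [3.0]])
        fm = normalize(X, "minmax01", fit_rows=np.array([True, True, True]))
        np.testing.assert_allclose(fm.values.ravel(), [0.0, 1.0, 0.5])

    def test_test_values_clipped_to_fit_range(self):
        X = np.array([[2.0], [4.0], [5.0], [1.0]])
        fit = np.array([True, True, False, False])
        fm = normalize(X, "minmax01", fit_rows=fit)
        np.testing.assert_allclose(fm.values.ravel(), [0.0, 1.0, 1.0, 0.0])

    def test_symmetric_mode_range(self):
        X = np.array([[0.0], [10.0]])
        fm = normalize(X, "symmetric11")
        np.testing.assert_allclose(fm.values.ravel(), [-1.0, 1.0])


class TestRegistryInvariants:
    def test_every_encoder_fixed_dimension_and_deterministic(self):
        cfg = EncoderConfig(max_lag=10, pseaac_lambda=8, qso_maxlag=10)
        registry = build_encoder_registry(cfg)
        seqs = random_sequences(5, 40, 150, seed=9)
        for name, enc in registry.items():
            dims = {np.asarray(enc(s)).ravel().shape for s in seqs}
            assert len(dims) == 1, name
            np.testing.assert_array_equal(enc(seqs[0]), enc(seqs[0]))

    def test_composition_family_nonnegative(self):
        for seq in ORACLE_SEQS[:10]:
            for vec in (encode_composition(seq, 1), encode_composition(seq, 2),
                        encode_conjoint_triad(seq),
                        encode_pseaac(seq, 8), encode_qso(seq, maxlag=10)):
                assert (vec >= 0).all()

    def test_property_table_standardization(self):
        props = default_properties()
        for name in props.names():
            vals = np.array([props.properties[name][a] for a in AA])
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std() - 1.0) < 1e-9

    def test_ws_ct_gap_one_equals_plain_ct(self):
        seq = ORACLE_SEQS[0]
        np.testing.assert_allclose(encode_ws_conjoint_triad(seq, max_gap=1),
                                   encode_conjoint_triad(seq))
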