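import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srpmotif import fixtures
from srpmotif.alphabet import (
    GAP,
    AnglePair,
    Codebook,
    SASM,
    build_sasm,
    compute_angles,
    encode,
    train_codebook,
)


# --- independent angle oracle: atan2-based, no shared code paths ------------

def oracle_angles(ca):
    """Brute-force (kappa, alpha) using atan2 forms instead of acos/explicit
    normal construction."""
    n = len(ca)
    out = []
    for i in range(n):
        if not (2 <= i <= n - 3):
            out.append((None, None))
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        kappa = math.degrees(
            math.atan2(np.linalg.norm(np.cross(u, v)), float(np.dot(u, v)))
        )
        b1 = ca[i] - ca[i - 1]
        b2 = ca[i + 1] - ca[i]
        b3 = ca[i + 2] - ca[i + 1]
        c12, c23 = np.cross(b1, b2), np.cross(b2, b3)
        if np.linalg.norm(c12) < 1e-8 or np.linalg.norm(c23) < 1e-8:
            alpha = None
        else:
            alpha = math.degrees(
                math.atan2(
                    float(np.dot(np.cross(c12, c23), b2)) / np.linalg.norm(b2),
                    float(np.dot(c12, c23)),
                )
            )
        out.append((kappa, alpha))
    return out


def test_angles_match_independent_oracle(rng):
    for _ in range(5):
        chain = fixtures.make_random_walk(25, rng_seed=int(rng.integers(2**31)))
        got = compute_angles(chain)
        expected = oracle_angles(chain.ca_coords())
        for g, (ek, ea) in zip(got, expected):
            if ek is None:
                assert g.kappa is None and g.alpha is None
            else:
                assert g.kappa == pytest.approx(ek, abs=1e-6)
                assert g.alpha == pytest.approx(ea, abs=1e-6)


def test_first_two_and_last_two_positions_undefined():
    chain = fixtures.make_varied_chain(20, rng_seed=1)
    angles = compute_angles(chain)
    for i in (0, 1, 18, 19):
        assert not angles[i].defined
    assert all(angles[i].defined for i in range(2, 18))


def test_encoding_invariant_under_rigid_motion(codebook, rng):
    """Structural letters are internal coordinates: any rotation+translation
    of the structure leaves the string unchanged."""
    from scipy.spatial.transform import Rotation

    chain = fixtures.make_varied_chain(40, rng_seed=8)
    reference = encode(chain, codebook).letters
    for _ in range(5):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-50, 50, 3)
        moved = fixtures.make_varied_chain(40, rng_seed=8)
        for res in moved.chain.residues if hasattr(moved, "chain") else moved.residues:
            for atom in res.atoms:
                atom.coords = R @ atom.coords + t
        assert encode(moved, codebook).letters == reference


class TestTrainCodebook:
    def test_k_distant_points_become_their_own_centroids(self):
        pairs = [AnglePair(kappa=10.0 * i, alpha=-170.0 + 15.0 * i) for i in range(18)]
        cb = train_codebook(pairs, k=18, rng_seed=0)
        got = sorted(cb.centroids)
        expected = sorted((p.kappa, p.alpha) for p in pairs)
        assert np.allclose(got, expected)

    def test_two_tight_clusters_recovered(self, rng):
        centers = [(30.0, 60.0), (150.0, -120.0)]
        pairs = []
        for kappa, alpha in centers:
            for _ in range(50):
                pairs.append(
                    AnglePair(
                        kappa=kappa + rng.normal(scale=2.0),
                        alpha=alpha + rng.normal(scale=2.0),
                    )
                )
        cb = train_codebook(pairs, k=2, rng_seed=0)
        for kappa, alpha in centers:
            d = min(
                math.hypot(ck - kappa, min(abs(ca - alpha), 360 - abs(ca - alpha)))
                for ck, ca in cb.centroids
            )
            assert d < 2.0  # within the cluster spread

    def test_deterministic_for_fixed_seed(self):
        angles = []
        for s in range(3):
            angles.extend(compute_angles(fixtures.make_varied_chain(40, rng_seed=s)))
        a = train_codebook(angles, rng_seed=5)
        b = train_codebook(angles, rng_seed=5)
        assert a.to_text() == b.to_text()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            train_codebook([AnglePair(kappa=1.0, alpha=1.0)] * 5, k=23)


class TestEncode:
    def test_ideal_helix_is_one_repeated_letter(self, codebook):
        sa = encode(fixtures.make_helix(20), codebook)
        interior = sa.letters.strip(GAP)
        assert len(set(interior)) == 1

    def test_short_chain_is_all_gaps(self, codebook):
        class FourResidues:
            chain_id = "A"

            def ca_coords(self):
                return np.arange(12, dtype=float).reshape(4, 3)

        assert encode(FourResidues(), codebook).letters == "----"

    def test_small_noise_keeps_90pct_letters(self, codebook):
        """Coordinate jitter at 0.1 A rarely crosses a codebook cell boundary;
        this underwrites the search's tolerance to flexible interfaces."""
        identities = []
        for seed in range(10):
            parent = fixtures.make_template_query(seed=seed)
            child = fixtures.perturb_homolog(parent, 0.1, 0.0, rng_seed=seed + 100)
            a = encode(parent.chain, codebook).letters.strip(GAP)
            b = encode(child.chain, codebook).letters.strip(GAP)
            identities.append(np.mean([x == y for x, y in zip(a, b)]))
        assert np.mean(identities) >= 0.9


class TestBuildSASM:
    def test_identical_strings_hand_computed_log_odds(self):
        """Closed-form check with one 'AAAA'/'AAAA' pair and +1 pseudocounts:
        276 cells, f_AA = 5, total 280; p_A = 16/280, p_B = 12/280 gives
        s_AA = round(2 log2(5*280/16^2)) = 5, s_AB = round(2 log2(280/384)) = -1.
        """
        sasm = build_sasm([("AAAA", "AAAA")])
        assert sasm.score("A", "A") == 5
        for other in "BCDEFGHIJKLMNOPQRSTUVW":
            assert sasm.score("A", other) == -1
            assert sasm.score("A", other) < sasm.score("A", "A")

    def test_uniform_random_letters_give_near_zero_scores(self, rng):
        letters = "ABCDEFGHIJKLMNOPQRSTUVW"
        pairs = []
        for _ in range(40):
            s1 = "".join(rng.choice(list(letters), 2000))
            s2 = "".join(rng.choice(list(letters), 2000))
            pairs.append((s1, s2))
        sasm = build_sasm(pairs)
        assert np.all(np.abs(sasm.scores) <= 1)
        assert np.mean(np.abs(sasm.scores)) < 0.5

    def test_matrix_symmetric_and_round_trips_serialization(self, sasm, tmp_path):
        assert np.array_equal(sasm.scores, sasm.scores.T)
        path = tmp_path / "sasm.tsv"
        sasm.save(path)
        back = SASM.load(path)
        assert np.array_equal(back.scores, sasm.scores)
        assert (back.gap_open, back.gap_extend) == (sasm.gap_open, sasm.gap_extend)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_sasm([])


def test_codebook_round_trips_serialization(codebook, tmp_path):
    path = tmp_path / "codebook.tsv"
    codebook.save(path)
    back = Codebook.load(path)
    assert back.letters == codebook.letters
    assert np.allclose(back.centroids, codebook.centroids, atol=1e-4)
    assert back.version_tag == codebook.version_tag
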