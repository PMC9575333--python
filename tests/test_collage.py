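import numpy as np
import pytest
from scipy import stats

from rdepth.collage import (CollageConfig, GradientVolumes,
                            collage_descriptor, collage_feature_names,
                            compute_gradients, dominant_orientations,
                            haralick_13, local_cooccurrence,
                            quantize_orientations)
from rdepth.deformation import first_order_stats
from rdepth.io import VolumeGrid

EPS = 1e-12


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(data=np.asarray(data, float),
                      affine=np.diag(list(spacing) + [1.0]))


# ---------------------------------------------------------------- gradients

class TestGradients:
    def test_linear_ramp(self):
        x = np.arange(5, dtype=float)
        data = 2.0 * x[:, None, None] * np.ones((5, 5, 5))
        g = compute_gradients(_vol(data))
        np.testing.assert_allclose(g.x, 2.0)
        np.testing.assert_allclose(g.y, 0.0)
        np.testing.assert_allclose(g.z, 0.0)

    def test_constant_volume(self):
        g = compute_gradients(_vol(np.full((4, 4, 4), 3.0)))
        for arr in (g.x, g.y, g.z):
            np.testing.assert_array_equal(arr, 0.0)

    def test_index_loop_oracle(self, rng):
        """Exact agreement with hand-indexed finite differences."""
        data = rng.standard_normal((6, 6, 6))
        spacing = (1.0, 2.0, 0.5)
        g = compute_gradients(_vol(data, spacing))
        for axis, garr, h in ((0, g.x, 1.0), (1, g.y, 2.0), (2, g.z, 0.5)):
            n = data.shape[axis]
            for idx in np.ndindex(*data.shape):
                i = idx[axis]
                lo = list(idx)
                hi = list(idx)
                if i == 0:
                    hi[axis] = 1
                    expected = (data[tuple(hi)] - data[idx]) / h
                elif i == n - 1:
                    lo[axis] = n - 2
                    expected = (data[idx] - data[tuple(lo)]) / h
                else:
                    lo[axis], hi[axis] = i - 1, i + 1
                    expected = (data[tuple(hi)] - data[tuple(lo)]) / (2 * h)
                assert garr[idx] == pytest.approx(expected, abs=1e-12)

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError):
            compute_gradients(_vol(np.zeros((1, 5, 5))))


# ------------------------------------------------------------- orientations

class TestDominantOrientations:
    def test_all_gradients_along_x(self):
        g = GradientVolumes(x=np.ones((5, 5, 5)), y=np.zeros((5, 5, 5)),
                            z=np.zeros((5, 5, 5)))
        om = dominant_orientations(g)
        np.testing.assert_allclose(om.theta, 0.0, atol=1e-12)
        np.testing.assert_allclose(om.phi, 0.0, atol=1e-12)
        assert om.valid.all()

    def test_all_gradients_along_y(self):
        g = GradientVolumes(x=np.zeros((5, 5, 5)), y=np.ones((5, 5, 5)),
                            z=np.zeros((5, 5, 5)))
        om = dominant_orientations(g)
        np.testing.assert_allclose(om.theta, np.pi / 2, atol=1e-12)
        np.testing.assert_allclose(om.phi, 0.0, atol=1e-12)

    def test_degenerate_window_flagged(self):
        g = GradientVolumes(*(np.zeros((5, 5, 5)),) * 3)
        om = dominant_orientations(g)
        assert not om.valid.any()
        np.testing.assert_array_equal(om.theta, 0.0)
        np.testing.assert_array_equal(om.phi, 0.0)

    def test_eigen_oracle(self, rng):
        """theta/phi match an explicit per-voxel eigen-decomposition of
        F^T F built from clipped windows, to 1e-8 in angle."""
        shape = (6, 6, 6)
        gx, gy, gz = rng.standard_normal((3,) + shape)
        cfg = CollageConfig(window_radius=1)
        om = dominant_orientations(GradientVolumes(gx, gy, gz), cfg)
        for idx in [(0, 0, 0), (2, 3, 1), (5, 5, 5), (3, 3, 3), (1, 4, 2)]:
            vecs = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        p = (idx[0] + di, idx[1] + dj, idx[2] + dk)
                        if all(0 <= a < n for a, n in zip(p, shape)):
                            vecs.append([gx[p], gy[p], gz[p]])
            f = np.asarray(vecs)
            w, v = np.linalg.eigh(f.T @ f)
            psi = v[:, np.argmax(w)]
            if psi[np.argmax(np.abs(psi))] < 0:
                psi = -psi
            theta = np.arctan(psi[1] / psi[0]) if psi[0] != 0 else np.pi / 2
            rho = np.hypot(psi[0], psi[1])
            phi = np.arctan(psi[2] / rho) if rho != 0 else np.pi / 2
            assert om.theta[idx] == pytest.approx(theta, abs=1e-8)
            assert om.phi[idx] == pytest.approx(phi, abs=1e-8)

    def test_intensity_rescale_invariance(self, rng):
        """Affine intensity rescaling leaves the orientation maps unchanged."""
        data = rng.standard_normal((7, 7, 7))
        om1 = dominant_orientations(compute_gradients(_vol(data)))
        om2 = dominant_orientations(
            compute_gradients(_vol(5.0 * data + 17.0)))
        np.testing.assert_allclose(om1.theta, om2.theta, atol=1e-9)
        np.testing.assert_allclose(om1.phi, om2.phi, atol=1e-9)


# ------------------------------------------------------------- quantization

class TestQuantization:
    def test_right_edge(self):
        assert quantize_orientations(np.array(np.pi / 2), 64) == 63

    def test_left_edge(self):
        assert quantize_orientations(np.array(-np.pi / 2 + 1e-9), 64) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantize_orientations(np.array(2.0), 64)

    def test_uniform_occupancy(self, rng):
        """Uniform angles give uniform bins within multinomial error."""
        n = 100_000
        angles = rng.uniform(-np.pi / 2 + 1e-9, np.pi / 2, size=n)
        bins = quantize_orientations(angles, 16)
        counts = np.bincount(bins, minlength=16)
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3


# ------------------------------------------------------------ co-occurrence

class TestLocalCooccurrence:
    def test_constant_window_is_diagonal_delta(self):
        q = np.full((7, 7, 7), 5, dtype=int)
        m = local_cooccurrence(q, (3, 3, 3), CollageConfig(
            n_orientation_bins=8))
        expected = np.zeros((8, 8))
        expected[5, 5] = 1.0
        np.testing.assert_allclose(m, expected)

    def test_alternating_strip_hand_count(self):
        """1D alternating bins, single offset (1,0,0): all mass off-diagonal
        and the matrix equals the hand-enumerated symmetric pair count."""
        q = np.zeros((7, 1, 1), dtype=int)
        q[1::2] = 1
        cfg = CollageConfig(n_orientation_bins=2,
                            cooccur_window_radius=2,
                            cooccur_offsets=((1, 0, 0),))
        m = local_cooccurrence(q, (3, 0, 0), cfg)
        # window covers x = 1..5 -> bins 1,0,1,0,1; ordered pairs at +1:
        # (1,0),(0,1),(1,0),(0,1) -> symmetric counts 4+4, normalized
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(m, expected)
        assert m[0, 0] == 0 and m[1, 1] == 0

    def test_symmetry(self, rng):
        q = rng.integers(0, 8, size=(9, 9, 9))
        m = local_cooccurrence(q, (4, 4, 4),
                               CollageConfig(n_orientation_bins=8))
        np.testing.assert_allclose(m, m.T)
        assert m.sum() == pytest.approx(1.0)

    def test_window_outside_image_rejected(self):
        q = np.zeros((5, 5, 5), dtype=int)
        with pytest.raises(ValueError):
            local_cooccurrence(q, (50, 50, 50), CollageConfig())


# ----------------------------------------------------------------- Haralick

def haralick_oracle(p):
    """Literal transcription of the 13 Haralick definitions (scalar loops)."""
    n = p.shape[0]
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(n))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(n))
    p_plus = [0.0] * (2 * n - 1)
    p_minus = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_plus[i + j] += p[i, j]
            p_minus[abs(i - j)] += p[i, j]
    energy = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    contrast = sum(k ** 2 * p_minus[k] for k in range(n))
    sig = (var_x * var_y) ** 0.5
    if sig > EPS:
        corr = (sum(i * j * p[i, j] for i in range(n) for j in range(n))
                - mu_x * mu_y) / sig
    else:
        corr = 0.0
    ssq = var_x
    idm = sum(p[i, j] / (1 + (i - j) ** 2)
              for i in range(n) for j in range(n))
    sum_avg = sum(k * p_plus[k] for k in range(2 * n - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_plus[k] for k in range(2 * n - 1))
    sum_ent = -sum(p_plus[k] * np.log(p_plus[k] + EPS)
                   for k in range(2 * n - 1))
    ent = -sum(p[i, j] * np.log(p[i, j] + EPS)
               for i in range(n) for j in range(n))
    mu_d = sum(k * p_minus[k] for k in range(n))
    diff_var = sum((k - mu_d) ** 2 * p_minus[k] for k in range(n))
    diff_ent = -sum(p_minus[k] * np.log(p_minus[k] + EPS) for k in range(n))
    hx = -sum(px[i] * np.log(px[i] + EPS) for i in range(n))
    hy = -sum(py[j] * np.log(py[j] + EPS) for j in range(n))
    hxy1 = -sum(p[i, j] * np.log(px[i] * py[j] + EPS)
                for i in range(n) for j in range(n))
    hxy2 = -sum(px[i] * py[j] * np.log(px[i] * py[j] + EPS)
                for i in range(n) for j in range(n))
    hmax = max(hx, hy)
    imc1 = (ent - hxy1) / hmax if hmax > EPS else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent))))
    return np.array([energy, contrast, corr, ssq, idm, sum_avg, sum_var,
                     sum_ent, ent, diff_var, diff_ent, imc1, imc2])


class TestHaralick13:
    def test_single_entry_diagonal(self):
        p = np.zeros((6, 6))
        p[2, 2] = 1.0
        h = haralick_13(p)
        assert h[0] == pytest.approx(1.0)          # energy
        assert h[1] == pytest.approx(0.0)          # contrast
        assert h[8] == pytest.approx(0.0, abs=1e-10)  # entropy

    def test_uniform_matrix_energy(self):
        n = 5
        h = haralick_13(np.full((n, n), 1.0 / n ** 2))
        assert h[0] == pytest.approx(1.0 / n ** 2)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick_13(np.ones((4, 4)))

    def test_formula_oracle_100_random(self, rng):
        """All 13 statistics match the literal-formula oracle to 1e-10
        on 100 random normalized symmetric matrices."""
        for _ in range(100):
            n = int(rng.integers(2, 9))
            m = rng.random((n, n))
            m = m + m.T
            m /= m.sum()
            np.testing.assert_allclose(haralick_13(m), haralick_oracle(m),
                                       atol=1e-10)

    def test_ranges(self, rng):
        """Energies in (0,1], entropies >= 0 for random matrices."""
        for _ in range(20):
            m = rng.random((8, 8))
            m = m + m.T
            m /= m.sum()
            h = haralick_13(m)
            assert 0 < h[0] <= 1
            for k in (7, 8, 10):
                assert h[k] >= -1e-12


# ------------------------------------------------------ compartment pipeline

class TestCollageDescriptor:
    def test_length_130_regardless_of_size(self, rng):
        vol = _vol(rng.standard_normal((10, 10, 10)))
        small = np.zeros((10, 10, 10), bool)
        small[5, 5, 5] = True
        large = np.zeros((10, 10, 10), bool)
        large[3:8, 3:8, 3:8] = True
        assert collage_descriptor(vol, small).shape == (130,)
        assert collage_descriptor(vol, large).shape == (130,)

    def test_feature_names(self):
        names = collage_feature_names("P")
        assert len(names) == 130
        assert names[0] == "collage_P_theta_energy_mean"
        assert names[-1] == "collage_P_phi_imc2_kurtosis"

    def test_constant_volume_degenerate(self):
        vol = _vol(np.full((9, 9, 9), 42.0))
        mask = np.zeros((9, 9, 9), bool)
        mask[3:6, 3:6, 3:6] = True
        vec, maps = collage_descriptor(vol, mask, return_maps=True)
        for angle in ("theta", "phi"):
            np.testing.assert_allclose(maps[(angle, "energy")], 1.0)
            np.testing.assert_allclose(maps[(angle, "entropy")], 0.0,
                                       atol=1e-10)
        names = collage_feature_names("T")
        std_idx = [i for i, nm in enumerate(names)
                   if "energy" in nm and nm.endswith("_std")]
        for i in std_idx:
            assert vec[i] == pytest.approx(0.0, abs=1e-12)

    def test_empty_compartment_rejected(self, rng):
        vol = _vol(rng.standard_normal((6, 6, 6)))
        from rdepth.deformation import EmptyRegionError
        with pytest.raises(EmptyRegionError):
            collage_descriptor(vol, np.zeros((6, 6, 6), bool))

    def test_loop_reference_oracle(self, rng):
        """Full per-voxel pipeline equals a naive nested-loop reference."""
        shape = (8, 8, 8)
        data = rng.standard_normal(shape)
        cfg = CollageConfig(window_radius=1, n_orientation_bins=8,
                            cooccur_window_radius=1)
        vol = _vol(data)
        mask = np.zeros(shape, bool)
        mask[3:6, 3:6, 2:5] = True
        vec = collage_descriptor(vol, mask, cfg)

        # --- reference: everything by explicit loops -------------------
        gx, gy, gz = np.gradient(data, 1.0, 1.0, 1.0)
        theta = np.zeros(shape)
        phi = np.zeros(shape)
        for idx in np.ndindex(*shape):
            vecs = []
            for off in np.ndindex(3, 3, 3):
                p = tuple(a + o - 1 for a, o in zip(idx, off))
                if all(0 <= a < n for a, n in zip(p, shape)):
                    vecs.append([gx[p], gy[p], gz[p]])
            f = np.asarray(vecs)
            m = f.T @ f
            if np.trace(m) <= 1e-20:
                continue
            w, v = np.linalg.eigh(m)
            psi = v[:, np.argmax(w)]
            if psi[np.argmax(np.abs(psi))] < 0:
                psi = -psi
            theta[idx] = (np.arctan(psi[1] / psi[0]) if psi[0] != 0
                          else np.pi / 2)
            rho = np.hypot(psi[0], psi[1])
            phi[idx] = (np.arctan(psi[2] / rho) if rho != 0 else np.pi / 2)

        def quant(a):
            h = np.pi / cfg.n_orientation_bins
            return min(max(int(np.ceil((a + np.pi / 2) / h)) - 1, 0),
                       cfg.n_orientation_bins - 1)

        ref_maps = {("theta", h): [] for h in cfg.haralick_names}
        ref_maps.update({("phi", h): [] for h in cfg.haralick_names})
        for angle, amap in (("theta", theta), ("phi", phi)):
            q = np.vectorize(quant)(amap)
            for idx in zip(*np.nonzero(mask)):
                nb = cfg.n_orientation_bins
                counts = np.zeros((nb, nb))
                r = cfg.cooccur_window_radius
                for off in cfg.cooccur_offsets:
                    for wo in np.ndindex(2 * r + 1, 2 * r + 1, 2 * r + 1):
                        a = tuple(c + w - r for c, w in zip(idx, wo))
                        b = tuple(x + o for x, o in zip(a, off))
                        in_win = all(abs(x - c) <= r
                                     for x, c in zip(b, idx))
                        in_img = all(0 <= x < n for x, n in
                                     zip(a, shape)) and all(
                                         0 <= x < n for x, n in
                                         zip(b, shape))
                        if in_win and in_img:
                            counts[q[a], q[b]] += 1
                counts = counts + counts.T
                counts /= counts.sum()
                hvals = haralick_oracle(counts)
                for hi, hname in enumerate(cfg.haralick_names):
                    ref_maps[(angle, hname)].append(hvals[hi])

        expected = []
        for angle in ("theta", "phi"):
            for hname in cfg.haralick_names:
                expected.extend(first_order_stats(
                    np.asarray(ref_maps[(angle, hname)])))
        np.testing.assert_allclose(vec, np.asarray(expected), atol=1e-9)
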