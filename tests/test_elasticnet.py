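"""Elastic-net deconvolution: design matrix, solver, grid, subtraction."""

import numpy as np
import pytest
from scipy.optimize import nnls

from ms2deconv import (
    Spectrum,
    build_design_matrix,
    grid_optimize,
    solve_elastic_net,
    subtract_contaminants,
)
from ms2deconv.candidates import CandidateSpectrum
from ms2deconv.elasticnet import lambda_path
from ms2deconv.scoring import dot_product_similarity


def _cand(spec, provenance="III", penalty=0.0, sim=float("nan")):
    return CandidateSpectrum(ion_mz=spec.precursor_mz, spectrum=spec,
                             provenance=provenance, penalty=penalty,
                             similarity_to_spectrum0=sim)


@pytest.fixture
def two_component_problem():
    rng = np.random.default_rng(3)
    a_mz = np.sort(rng.uniform(60, 280, 6))
    b_mz = np.sort(rng.uniform(60, 280, 5))
    A = Spectrum(mz=a_mz, intensity=rng.uniform(20, 100, 6), precursor_mz=300.0).normalized()
    B = Spectrum(mz=b_mz, intensity=rng.uniform(20, 100, 5), precursor_mz=300.3).normalized()
    w = 0.7
    spec0 = Spectrum(
        mz=np.concatenate([A.mz, B.mz]),
        intensity=np.concatenate([w * A.intensity, (1 - w) * B.intensity]),
        precursor_mz=300.0,
    )
    problem = build_design_matrix(
        spec0, [_cand(A, "MAIN"), _cand(B, "III")], mz_tol=0.01
    )
    return spec0, problem, A, B, w


class TestDesignMatrix:
    def test_single_candidate_column_proportional_to_response(self, simple_spectrum):
        problem = build_design_matrix(
            simple_spectrum, [_cand(simple_spectrum.normalized(), "MAIN")], 0.01
        )
        col = problem.X[:, 0]
        ratio = problem.y / col
        np.testing.assert_allclose(ratio, ratio[0])

    def test_disjoint_candidates_give_orthogonal_columns(self):
        spec0 = Spectrum(mz=[100.0, 200.0], intensity=[50.0, 50.0], precursor_mz=300.0)
        a = Spectrum(mz=[100.0], intensity=[100.0], precursor_mz=300.0)
        b = Spectrum(mz=[200.0], intensity=[100.0], precursor_mz=300.3)
        problem = build_design_matrix(spec0, [_cand(a, "MAIN"), _cand(b)], 0.01)
        assert problem.X[:, 0] @ problem.X[:, 1] == pytest.approx(0.0)

    def test_axis_matches_brute_force_union(self):
        rng = np.random.default_rng(11)
        mz_tol = 0.01
        spectra = [
            Spectrum(mz=np.sort(rng.uniform(50, 500, 8)),
                     intensity=rng.uniform(1, 100, 8), precursor_mz=550.0)
            for _ in range(3)
        ]
        problem = build_design_matrix(
            spectra[0], [_cand(spectra[1], "MAIN"), _cand(spectra[2])], mz_tol
        )
        all_mz = np.sort(np.concatenate([s.mz for s in spectra]))
        n_groups = 1 + int(np.sum(np.diff(all_mz) > mz_tol))
        assert len(problem.axis) == n_groups

    def test_requires_main_column(self, simple_spectrum):
        with pytest.raises(ValueError, match="MAIN"):
            build_design_matrix(simple_spectrum, [_cand(simple_spectrum)], 0.01)

    def test_empty_spectrum0_rejected(self, simple_spectrum):
        empty = Spectrum(mz=[], intensity=[], precursor_mz=100.0)
        with pytest.raises(ValueError):
            build_design_matrix(empty, [_cand(simple_spectrum, "MAIN")], 0.01)

    def test_class_iv_penalty_factor(self, simple_spectrum):
        iv = _cand(simple_spectrum.normalized(), "IV", penalty=4.0, sim=0.6)
        problem = build_design_matrix(
            simple_spectrum, [_cand(simple_spectrum.normalized(), "MAIN"), iv], 0.01
        )
        np.testing.assert_allclose(problem.penalty_factors, [1.0, 5.0])


class TestSolver:
    def test_matches_nnls_oracle_at_zero_penalty(self, two_component_problem):
        _, problem, *_ = two_component_problem
        sol = solve_elastic_net(problem, alpha=0.0, lam=0.0)
        beta_oracle, _ = nnls(problem.X, problem.y)
        assert np.max(np.abs(sol.beta - beta_oracle)) < 1e-4

    def test_zero_response_gives_zero_beta(self, two_component_problem):
        _, problem, *_ = two_component_problem
        problem.y = np.zeros_like(problem.y)
        sol = solve_elastic_net(problem, 0.5, 0.1)
        np.testing.assert_allclose(sol.beta, 0.0)

    def test_huge_lambda_shrinks_to_zero(self, two_component_problem):
        _, problem, *_ = two_component_problem
        sol = solve_elastic_net(problem, 0.5, 1e9)
        np.testing.assert_allclose(sol.beta, 0.0, atol=1e-8)

    def test_beta_always_nonnegative(self, two_component_problem):
        _, problem, *_ = two_component_problem
        for alpha in (0.0, 0.5, 1.0):
            for lam in lambda_path(problem):
                sol = solve_elastic_net(problem, alpha, float(lam))
                assert np.all(sol.beta >= 0)

    def test_invalid_alpha_rejected(self, two_component_problem):
        _, problem, *_ = two_component_problem
        with pytest.raises(ValueError):
            solve_elastic_net(problem, 1.5, 0.1)


class TestGrid:
    def test_exactly_110_combinations_evaluated(self, two_component_problem):
        _, problem, *_ = two_component_problem
        sol = grid_optimize(problem)
        assert sol.n_evaluated == 110
        alphas = {round(s.alpha, 1) for s in sol.all_solutions}
        lams = {s.lam for s in sol.all_solutions}
        assert len(alphas) == 11 and len(lams) == 10

    def test_winner_has_minimal_residue(self, two_component_problem):
        _, problem, *_ = two_component_problem
        sol = grid_optimize(problem)
        assert all(sol.residue <= s.residue for s in sol.all_solutions)

    def test_pure_response_puts_weight_on_matching_column(self):
        spec0 = Spectrum(mz=[100.0, 150.0], intensity=[100.0, 50.0], precursor_mz=300.0)
        other = Spectrum(mz=[200.0], intensity=[100.0], precursor_mz=300.3)
        problem = build_design_matrix(
            spec0, [_cand(spec0.normalized(), "MAIN"), _cand(other)], 0.01
        )
        sol = grid_optimize(problem)
        assert sol.beta[0] > 0
        assert sol.beta[1] == pytest.approx(0.0, abs=1e-6)
        # smallest path lambda is lambda_max/1000, so a whisper of shrinkage
        # bias remains; residue must still be tiny relative to ||y||^2
        assert sol.residue < 1e-5 * float(problem.y @ problem.y)

    def test_noiseless_mixture_weights_recovered(self, two_component_problem):
        _, problem, A, B, w = two_component_problem
        sol = grid_optimize(problem)
        braw = sol.beta_raw(problem)
        ratio = braw[0] / braw[1]
        assert ratio == pytest.approx(w / (1 - w), rel=0.05)


class TestSubtraction:
    def test_zero_contaminant_beta_returns_normalized_spectrum0(self):
        spec0 = Spectrum(mz=[100.0, 150.0], intensity=[100.0, 50.0], precursor_mz=300.0)
        other = Spectrum(mz=[200.0], intensity=[100.0], precursor_mz=300.3)
        problem = build_design_matrix(
            spec0, [_cand(spec0.normalized(), "MAIN"), _cand(other)], 0.01
        )
        sol = grid_optimize(problem)
        out, failed = subtract_contaminants(spec0, problem, sol)
        assert not failed
        assert len(out) == 2
        assert out.base_peak_intensity == 100.0

    def test_zero_main_beta_fails_and_passes_through(self, two_component_problem):
        spec0, problem, *_ = two_component_problem
        sol = grid_optimize(problem)
        sol.beta = sol.beta.copy()
        sol.beta[problem.main_index] = 0.0
        out, failed = subtract_contaminants(spec0, problem, sol)
        assert failed
        assert len(out) == len(spec0)

    def test_subtraction_moves_spectrum_toward_truth(self, two_component_problem):
        spec0, problem, A, B, w = two_component_problem
        sol = grid_optimize(problem)
        cleaned, failed = subtract_contaminants(spec0, problem, sol)
        assert not failed
        assert dot_product_similarity(cleaned, A) > dot_product_similarity(spec0, A)

    def test_output_intensities_nonnegative(self, two_component_problem):
        spec0, problem, *_ = two_component_problem
        sol = grid_optimize(problem)
        cleaned, _ = subtract_contaminants(spec0, problem, sol)
        assert np.all(cleaned.intensity >= 0)


class TestDeterminism:
    def test_identical_inputs_identical_solution(self, two_component_problem):
        _, problem, *_ = two_component_problem
        s1 = grid_optimize(problem)
        s2 = grid_optimize(problem)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        assert (s1.alpha, s1.lam) == (s2.alpha, s2.lam)
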