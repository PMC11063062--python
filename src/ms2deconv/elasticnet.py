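"""Penalized elastic-net deconvolution of chimeric MS2 spectra.

The chimeric spectrum ("Spectrum 0") is modeled as a non-negative mixture of
candidate component spectra on a shared m/z axis:

    Residue = min_beta  sum((y - X beta)^2) + lambda * sum_j pf_j * P_alpha(beta_j)
    P_alpha(b) = 0.5 * (1 - alpha) * b^2 + alpha * |b|

solved by cyclic coordinate descent under beta >= 0.  An 11 x 10 grid of
(alpha, lambda) combinations — alpha from 0 to 1 in steps of 0.1, lambda on a
log-spaced path of 10 values spanning three decades below lambda_max
(estimated from the column-response correlations) — yields 110 solutions; the
one with minimal residue (unpenalized RSS) wins.  Per-column penalty factors
pf_j inflate the shrinkage of transformation-network predictions (class IV).

After solving, the contamination components' fitted contributions are
subtracted from Spectrum 0; if nothing survives or the main ion's coefficient
is zero, the deconvolution is marked failed and Spectrum 0 passes through
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateSpectrum, assemble_candidates, select_library_candidate
from .chimera import assess_chimeric, assign_ms2_to_features, merge_coassigned_spectra
from .library import SpectralLibrary
from .spectrum import MS1Feature, RunData, Spectrum, normalize_spectrum

logger = logging.getLogger(__name__)

N_ALPHA = 11
N_LAMBDA = 10
LAMBDA_DECADES = 3.0
CONVERGENCE_TOL = 1e-6
MAX_SWEEPS = 10_000


@dataclass
class DeconvolutionProblem:
    """Aligned regression problem: response y (Spectrum 0) and one column per
    candidate spectrum, all on the merged m/z axis."""

    y: np.ndarray
    X: np.ndarray  # columns scaled to unit Euclidean norm
    axis: np.ndarray
    candidates: list[CandidateSpectrum]
    penalty_factors: np.ndarray
    column_norms: np.ndarray  # pre-normalization norms, to rescale beta

    @property
    def main_index(self) -> int:
        for j, c in enumerate(self.candidates):
            if c.provenance == "MAIN":
                return j
        raise ValueError("problem has no MAIN column")


@dataclass
class DeconvolutionSolution:
    beta: np.ndarray  # coefficients on the unit-norm columns
    alpha: float
    lam: float
    residue: float  # unpenalized RSS, the grid-selection criterion
    objective: float  # RSS + lambda * sum_j pf_j * P_alpha(beta_j)
    converged: bool = True
    failed: bool = False
    n_evaluated: int = 1
    all_solutions: list = field(default_factory=list, repr=False)

    def beta_raw(self, problem: DeconvolutionProblem) -> np.ndarray:
        """Coefficients rescaled to the original (un-normalized) columns."""
        return self.beta / problem.column_norms


def build_design_matrix(
    spectrum0: Spectrum,
    candidates: list[CandidateSpectrum],
    mz_tol: float = 0.01,
) -> DeconvolutionProblem:
    """Align Spectrum 0 and all candidates on a merged m/z axis.

    The axis is the union of all fragment m/z values merged at ``mz_tol``;
    absent peaks contribute zeros.  Columns are normalized to unit Euclidean
    norm (norms retained for rescaling beta).
    """
    if len(spectrum0) == 0:
        raise ValueError("Spectrum 0 is empty")
    if not candidates:
        raise ValueError("no candidate spectra supplied")
    if not any(c.provenance == "MAIN" for c in candidates):
        raise ValueError("a MAIN candidate column is required")
    spectra = [spectrum0] + [c.spectrum for c in candidates]
    all_mz = np.concatenate([s.mz for s in spectra])
    order = np.argsort(all_mz, kind="stable")
    all_mz = all_mz[order]
    groups = np.concatenate([[0], np.cumsum(np.diff(all_mz) > mz_tol)])
    n_bins = groups[-1] + 1
    # representative bin m/z = mean of members
    axis = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    np.add.at(axis, groups, all_mz)
    np.add.at(counts, groups, 1.0)
    axis /= counts

    def project(s: Spectrum) -> np.ndarray:
        v = np.zeros(n_bins)
        for mz, inten in zip(s.mz, s.intensity):
            j = int(np.argmin(np.abs(axis - mz)))
            v[j] += inten
        return v

    y = project(spectrum0)
    X = np.column_stack([project(c.spectrum) for c in candidates])
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    X = X / norms
    pf = np.array([1.0 + c.penalty if c.provenance == "IV" else 1.0 for c in candidates])
    return DeconvolutionProblem(
        y=y, X=X, axis=axis, candidates=candidates,
        penalty_factors=pf, column_norms=norms,
    )


def _elastic_net_objective(problem, beta, alpha, lam) -> tuple[float, float]:
    resid = problem.y - problem.X @ beta
    rss = float(resid @ resid)
    pen = float(np.sum(problem.penalty_factors * (
        0.5 * (1.0 - alpha) * beta ** 2 + alpha * np.abs(beta)
    )))
    return rss, rss + lam * pen


def solve_elastic_net(
    problem: DeconvolutionProblem,
    alpha: float,
    lam: float,
    beta0: np.ndarray | None = None,
) -> DeconvolutionSolution:
    """Cyclic coordinate descent for the non-negative penalized elastic net.

    Converges when the largest coefficient change in a sweep drops below
    1e-6, capped at 10^4 sweeps (non-convergence is flagged, not raised).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X, y, pf = problem.X, problem.y, problem.penalty_factors
    n_col = X.shape[1]
    beta = np.zeros(n_col) if beta0 is None else beta0.copy()
    xty = X.T @ y
    gram = X.T @ X  # columns are unit-norm: diagonal of ones
    converged = False
    for _ in range(MAX_SWEEPS):
        max_delta = 0.0
        for j in range(n_col):
            rho = xty[j] - gram[j] @ beta + beta[j]  # x_j' (y - X beta + x_j beta_j)
            num = 2.0 * rho - lam * pf[j] * alpha
            den = 2.0 + lam * pf[j] * (1.0 - alpha)
            new = max(0.0, num / den)
            delta = abs(new - beta[j])
            if delta > max_delta:
                max_delta = delta
            beta[j] = new
        if max_delta < CONVERGENCE_TOL:
            converged = True
            break
    if not converged:
        logger.warning(
            "elastic net did not converge (alpha=%.2f, lambda=%.4g)", alpha, lam
        )
    rss, obj = _elastic_net_objective(problem, beta, alpha, lam)
    return DeconvolutionSolution(
        beta=beta, alpha=alpha, lam=lam, residue=rss, objective=obj, converged=converged,
    )


def lambda_path(problem: DeconvolutionProblem) -> np.ndarray:
    """Log-spaced path of 10 lambda values over three decades below
    lambda_max = max_j |x_j' y| / len(y)."""
    lam_max = float(np.max(np.abs(problem.X.T @ problem.y))) / len(problem.y)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 10 ** (-LAMBDA_DECADES), N_LAMBDA)


def grid_optimize(problem: DeconvolutionProblem) -> DeconvolutionSolution:
    """Evaluate all 110 (alpha, lambda) combinations and return the solution
    with minimal residue (RSS); ties prefer larger lambda, then larger alpha
    (the sparser model)."""
    alphas = np.round(np.linspace(0.0, 1.0, N_ALPHA), 1)
    lams = lambda_path(problem)
    solutions: list[DeconvolutionSolution] = []
    for alpha in alphas:
        warm = None
        for lam in lams:  # descending path: warm starts carry over
            sol = solve_elastic_net(problem, float(alpha), float(lam), beta0=warm)
            warm = sol.beta
            solutions.append(sol)
    best = min(solutions, key=lambda s: (s.residue, -s.lam, -s.alpha))
    best.n_evaluated = len(solutions)
    best.all_solutions = solutions
    return best


def subtract_contaminants(
    spectrum0: Spectrum,
    problem: DeconvolutionProblem,
    solution: DeconvolutionSolution,
    floor: float = 0.005,
) -> tuple[Spectrum, bool]:
    """Remove the fitted contamination contributions from Spectrum 0.

    Per axis bin the remaining intensity is max(0, y − Σ_contam β_c·x_c);
    bins below ``floor`` × the surviving base peak are dropped and the result
    normalized.  Fails (returning Spectrum 0 unchanged) when the main-ion
    coefficient is zero or no fragment survives.
    """
    main = problem.main_index
    beta = solution.beta
    if beta[main] <= 0:
        logger.warning("deconvolution failed: main-ion coefficient is zero")
        return normalize_spectrum(spectrum0), True
    contamination = np.zeros_like(problem.y)
    for j in range(problem.X.shape[1]):
        if j != main:
            contamination += beta[j] * problem.X[:, j]
    remaining = np.maximum(0.0, problem.y - contamination)
    if remaining.max() > 0:
        remaining[remaining < floor * remaining.max()] = 0.0
    keep = (remaining > 0) & (problem.y > 0)
    if not keep.any():
        logger.warning("deconvolution failed: no fragment left after cleaning")
        return normalize_spectrum(spectrum0), True
    out = spectrum0.with_peaks(problem.axis[keep], remaining[keep])
    return normalize_spectrum(out), False


@dataclass
class DdaOptions:
    """Tunables of the DDA deconvolution pipeline."""

    ppm_tol: float = 10.0  # precursor / library matching tolerance, ppm
    rt_tol: float = 15.0  # feature RT half-window, seconds
    mz_tol: float = 0.01  # fragment merge tolerance, Th
    intensity_threshold: float = 1e4  # chimera acquisition threshold, abundance
    similarity: str = "dot_product"
    floor: float = 0.005  # post-subtraction relative intensity floor
    charge_max: int = 2
    deconvolve: bool = True  # False reproduces the no-deconvolution arm


@dataclass
class DeconvolutionReport:
    feature: MS1Feature
    spectrum: Spectrum | None
    is_chimeric: bool = False
    deconvolved: bool = False
    failed: bool = False
    n_candidates: int = 0
    solution: DeconvolutionSolution | None = None
    skipped: bool = False


def deconvolve_feature(
    feature: MS1Feature,
    spectra: list[Spectrum],
    run: RunData,
    library: SpectralLibrary | None,
    options: DdaOptions = DdaOptions(),
) -> DeconvolutionReport:
    """Deconvolve one feature given its assigned MS2 scans."""
    if not spectra:
        logger.info("feature %s: no MS2 scans assigned; skipped", feature.feature_id)
        return DeconvolutionReport(feature=feature, spectrum=None, skipped=True)
    spectrum0 = merge_coassigned_spectra(spectra, options.mz_tol)
    spectrum0.precursor_mz = feature.mz_med
    if np.isnan(spectrum0.precursor_rt):
        spectrum0.precursor_rt = feature.rt_med
    assessment = assess_chimeric(feature, spectrum0, run, options.intensity_threshold)
    if not assessment.is_chimeric or not options.deconvolve:
        return DeconvolutionReport(
            feature=feature, spectrum=normalize_spectrum(spectrum0),
            is_chimeric=assessment.is_chimeric,
        )
    contaminant_candidates = assemble_candidates(
        assessment, run, library,
        ppm_tol=options.ppm_tol, similarity=options.similarity,
        mz_tol=options.mz_tol, charge_max=options.charge_max,
        rt_tol=options.rt_tol, intensity_threshold=options.intensity_threshold,
    )
    if not contaminant_candidates:
        logger.warning(
            "feature %s: chimeric but no contaminant candidate; spectrum kept as is",
            feature.feature_id,
        )
        return DeconvolutionReport(
            feature=feature, spectrum=normalize_spectrum(spectrum0),
            is_chimeric=True, failed=True,
        )
    main_candidate = None
    if library is not None:
        main_candidate = select_library_candidate(
            assessment.main_ion[0], library, spectrum0,
            options.ppm_tol, options.similarity, options.mz_tol,
        )
    if main_candidate is not None:
        main_candidate = CandidateSpectrum(
            ion_mz=assessment.main_ion[0], spectrum=main_candidate.spectrum,
            provenance="MAIN",
        )
    else:
        main_candidate = CandidateSpectrum(
            ion_mz=assessment.main_ion[0], spectrum=normalize_spectrum(spectrum0),
            provenance="MAIN",
        )
    candidates = [main_candidate] + contaminant_candidates
    problem = build_design_matrix(spectrum0, candidates, options.mz_tol)
    solution = grid_optimize(problem)
    cleaned, failed = subtract_contaminants(spectrum0, problem, solution, options.floor)
    solution.failed = failed
    return DeconvolutionReport(
        feature=feature, spectrum=cleaned, is_chimeric=True, deconvolved=not failed,
        failed=failed, n_candidates=len(candidates), solution=solution,
    )


def deconvolve_dda(
    features: list[MS1Feature],
    run: RunData,
    library: SpectralLibrary | None,
    options: DdaOptions = DdaOptions(),
) -> dict[str, DeconvolutionReport]:
    """Full DDA pipeline: assign MS2 scans, merge, assess, deconvolve.

    Clean spectra bypass the regression and are returned normalized; features
    with no assigned MS2 are skipped with a log entry.
    """
    assignment = assign_ms2_to_features(run, features, options.ppm_tol, options.rt_tol)
    return {
        f.feature_id: deconvolve_feature(f, assignment[f.feature_id], run, library, options)
        for f in features
    }
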