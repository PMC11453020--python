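"""Pan/core rarefaction curves and pan-genome openness modeling.

For each sample size ``n`` from 1 to N, individuals are drawn uniformly
without replacement (200 independent draws per ``n`` by default); the
pan size is the number of genes present in at least one sampled
individual and the core size the number present in all of them.  The
mean pan curve is then fit with a bounded-exponential saturation model

    P(n) = A - B * exp(-n / tau)

whose asymptote ``A`` is the estimated total pan-genome size.  A Heaps
power law ``P(n) = D * n**gamma`` is fit alongside (on n >= 2); the pool
is called *open* when the observed curve is still visibly below the
asymptote at n = N or the Heaps exponent exceeds 0.02.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "RarefactionResult",
    "PanModelFit",
    "rarefy",
    "fit_pan_model",
    "write_rarefaction",
    "read_rarefaction",
]


@dataclass
class RarefactionResult:
    sample_sizes: np.ndarray        # shape (S,)
    pan: np.ndarray                 # shape (S, I) pan sizes per iteration
    core: np.ndarray                # shape (S, I)
    seed: int
    iterations: int

    def __post_init__(self) -> None:
        if np.any(self.pan < self.core):
            raise ValueError("pan size below core size")

    @property
    def pan_mean(self) -> np.ndarray:
        return self.pan.mean(axis=1)

    @property
    def pan_sd(self) -> np.ndarray:
        return self.pan.std(axis=1, ddof=0)

    @property
    def core_mean(self) -> np.ndarray:
        return self.core.mean(axis=1)

    @property
    def core_sd(self) -> np.ndarray:
        return self.core.std(axis=1, ddof=0)


@dataclass
class PanModelFit:
    model_form: str = "bounded_exponential"
    asymptote: float = math.nan      # A: estimated total pan-genome size (genes)
    amplitude: float = math.nan      # B
    tau: float = math.nan            # saturation rate (individuals)
    heaps_gamma: float = math.nan    # Heaps exponent
    heaps_coeff: float = math.nan    # Heaps D
    openness_verdict: str = "unknown"
    converged: bool = False
    message: str = ""
    residual_rms: float = math.nan

    def as_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "asymptote": self.asymptote,
            "amplitude": self.amplitude,
            "tau": self.tau,
            "heaps_gamma": self.heaps_gamma,
            "heaps_coeff": self.heaps_coeff,
            "openness_verdict": self.openness_verdict,
            "converged": self.converged,
            "message": self.message,
            "residual_rms": self.residual_rms,
        }


def rarefy(matrix: pd.DataFrame, iterations: int = 200, seed: int = 0,
           stride: int = 1) -> RarefactionResult:
    """Pan/core accumulation by repeated random subsampling of individuals.

    Each iteration draws one random ordering of the cohort and reads the
    pan/core sizes off its prefixes, so every (n, iteration) cell is a
    uniform without-replacement sample of n individuals and the curves
    are monotone within each iteration (pan never shrinks, core never
    grows, as individuals accumulate).  ``stride`` subsamples the grid
    of sample sizes for very large cohorts; the default evaluates every
    n from 1 to N.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    values = matrix.to_numpy(dtype=bool)
    n_genes, n_individuals = values.shape
    if n_individuals < 1:
        raise ValueError("matrix has no individuals")
    sizes = np.arange(1, n_individuals + 1, stride)
    if sizes[-1] != n_individuals:
        sizes = np.append(sizes, n_individuals)
    rng = np.random.default_rng(seed)
    keep = sizes - 1  # row of the cumulative arrays for each sample size
    pan = np.empty((len(sizes), iterations), dtype=np.int64)
    core = np.empty((len(sizes), iterations), dtype=np.int64)
    for it in range(iterations):
        order = rng.permutation(n_individuals)
        shuffled = values[:, order]
        cum_any = np.logical_or.accumulate(shuffled, axis=1)
        cum_all = np.logical_and.accumulate(shuffled, axis=1)
        pan[:, it] = cum_any.sum(axis=0)[keep]
        core[:, it] = cum_all.sum(axis=0)[keep]
    return RarefactionResult(sample_sizes=sizes, pan=pan, core=core,
                             seed=seed, iterations=iterations)


def _bounded_exp(n, a, b, tau):
    return a - b * np.exp(-n / tau)


def fit_pan_model(result: RarefactionResult) -> PanModelFit:
    """Fit the saturation model and the Heaps power law to the mean pan curve.

    Non-convergence is reported in the returned fit (``converged=False``
    with diagnostics in ``message``); no fallback values are invented.
    """
    sizes = result.sample_sizes.astype(float)
    pan_mean = result.pan_mean
    if len(sizes) < 4:
        return PanModelFit(converged=False,
                           message=f"need >= 4 sample sizes, got {len(sizes)}")
    fit = PanModelFit()
    max_pan = float(pan_mean.max())

    # Heaps exponent on n >= 2 (log-log linear regression)
    mask = (sizes >= 2) & (pan_mean > 0)
    if mask.sum() >= 2:
        lr = scipy.stats.linregress(np.log(sizes[mask]), np.log(pan_mean[mask]))
        fit.heaps_gamma = float(lr.slope)
        fit.heaps_coeff = float(np.exp(lr.intercept))

    if float(np.ptp(pan_mean)) == 0.0:
        # perfectly flat curve: the model degenerates to A = observed, B = 0
        fit.asymptote = max_pan
        fit.amplitude = 0.0
        fit.tau = 1.0
        fit.converged = True
        fit.residual_rms = 0.0
    else:
        a0 = max_pan + max(max_pan - float(pan_mean[len(pan_mean) // 2]), 1.0) * 0.1
        b0 = max(a0 - float(pan_mean[0]), 1.0)
        tau0 = max(float(sizes[-1]) / 5.0, 1.0)
        try:
            popt, _ = scipy.optimize.curve_fit(
                _bounded_exp, sizes, pan_mean,
                p0=(a0, b0, tau0),
                bounds=([max_pan, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            fit.converged = False
            fit.message = f"saturation fit did not converge: {exc}"
            fit.openness_verdict = "unknown"
            return fit
        fit.asymptote, fit.amplitude, fit.tau = (float(x) for x in popt)
        fit.converged = True
        resid = pan_mean - _bounded_exp(sizes, *popt)
        fit.residual_rms = float(np.sqrt(np.mean(resid**2)))

    still_rising = float(pan_mean[-1]) < 0.99 * fit.asymptote
    heaps_open = (not math.isnan(fit.heaps_gamma)) and fit.heaps_gamma > 0.02
    fit.openness_verdict = "open" if (still_rising or heaps_open) else "closed"
    return fit


def write_rarefaction(result: RarefactionResult, fit: PanModelFit | None, path) -> None:
    """TSV report: ``#fit`` header block, then per-n mean/SD rows."""
    with open(path, "w") as handle:
        if fit is None:
            handle.write("#fit\tstatus=failed\n")
        else:
            status = "ok" if fit.converged else "failed"
            handle.write(f"#fit\tstatus={status}\n")
            for key, value in fit.as_dict().items():
                handle.write(f"#fit\t{key}={value}\n")
        handle.write("n\tpan_mean\tpan_sd\tcore_mean\tcore_sd\n")
        for i, n in enumerate(result.sample_sizes):
            handle.write(
                f"{int(n)}\t{float(result.pan_mean[i])!r}\t{float(result.pan_sd[i])!r}"
                f"\t{float(result.core_mean[i])!r}\t{float(result.core_sd[i])!r}\n"
            )


def read_rarefaction(path) -> tuple[pd.DataFrame, dict]:
    """Re-read a rarefaction report: (per-n table, fit-summary dict)."""
    fit_info: dict[str, str] = {}
    rows = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#fit"):
                payload = line.rstrip("\n").split("\t", 1)[1]
                if "=" in payload:
                    key, value = payload.split("=", 1)
                    fit_info[key] = value
            elif line.startswith("n\t"):
                continue
            elif line.strip():
                n, pm, ps, cm, cs = line.rstrip("\n").split("\t")
                rows.append((int(n), float(pm), float(ps), float(cm), float(cs)))
    table = pd.DataFrame(rows, columns=["n", "pan_mean", "pan_sd", "core_mean", "core_sd"])
    return table, fit_info
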