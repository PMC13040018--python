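"""1:1 Langmuir SPR binding kinetics: simulation, global fitting, KD ranking.

The model is the textbook pseudo-first-order bimolecular interaction between
an immobilized ligand and an analyte at constant concentration C:

    association (0 <= t <= t_assoc):
        R(t) = Rmax * ka*C / (ka*C + kd) * (1 - exp(-(ka*C + kd) * t))
    dissociation (t > t_assoc):
        R(t) = R(t_assoc) * exp(-kd * (t - t_assoc))

with association rate ka (1/(M s)), dissociation rate kd (1/s), and the
equilibrium dissociation constant KD = kd/ka (M).  Because the 1:1 model has
a closed form, simulation is exact (no ODE solver) and fitting is global
nonlinear least squares over all concentrations simultaneously with shared
(ka, kd, Rmax), the way a biosensor evaluation package fits a
multi-concentration titration series.

Fitting follows the estimator-object convention: build a
:class:`LangmuirModel` from sensorgrams, call :meth:`~LangmuirModel.fit`, and
read estimates, standard errors and diagnostics off the returned
:class:`LangmuirResults` (or print ``results.summary()``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "Sensorgram",
    "LangmuirModel",
    "LangmuirResults",
    "kd_from_rates",
    "simulate_sensorgram",
    "fit_kinetics",
    "rank_by_affinity",
    "load_kinetics_table",
    "load_reference_kinetics",
    "read_sensorgram",
    "write_sensorgram",
]


@dataclass(frozen=True)
class KineticParams:
    """1:1 Langmuir rate constants; KD is derived, never stored separately."""

    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float = 100.0  # response units

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and Rmax must all be positive")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant, M."""
        return self.kd / self.ka

    @property
    def KD_nM(self) -> float:
        return self.KD * 1e9


@dataclass
class Sensorgram:
    """One response trace at a single analyte concentration."""

    times: np.ndarray        # s, strictly increasing, starting at 0
    responses: np.ndarray    # response units
    analyte_conc: float      # M
    t_assoc: float           # association phase end, s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.responses.shape:
            raise ValueError("times and responses must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.analyte_conc < 0:
            raise ValueError("analyte concentration must be non-negative")


def kd_from_rates(ka: float, kd: float) -> float:
    """KD in nM from ka (1/(M s)) and kd (1/s): (kd/ka) * 1e9."""
    if ka <= 0 or kd <= 0:
        raise ValueError("rate constants must be positive")
    return kd / ka * 1e9


def langmuir_response(times: np.ndarray, params: KineticParams,
                      conc: float, t_assoc: float) -> np.ndarray:
    """Closed-form 1:1 response at the given time points (noise-free)."""
    t = np.asarray(times, dtype=float)
    kobs = params.ka * conc + params.kd
    req = params.rmax * params.ka * conc / kobs if conc > 0 else 0.0
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-params.kd * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def simulate_sensorgram(params: KineticParams, conc: float,
                        t_assoc: float = 600.0, t_dissoc: float = 900.0,
                        dt: float = 5.0, noise_sd: float = 0.0,
                        seed: int | np.random.Generator | None = None
                        ) -> Sensorgram:
    """Simulate one trace; Gaussian noise of the given SD is added pointwise
    (``noise_sd=0`` gives the exact closed form)."""
    if t_assoc <= 0 or t_dissoc < 0 or dt <= 0:
        raise ValueError("t_assoc and dt must be positive, t_dissoc non-negative")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    responses = langmuir_response(times, params, conc, t_assoc)
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        responses = responses + rng.normal(0.0, noise_sd, size=times.shape)
    return Sensorgram(times, responses, conc, t_assoc)


# ---------------------------------------------------------------------------
# fitting


class LangmuirModel:
    """Global 1:1 Langmuir model over a multi-concentration sensorgram set.

    Parameters
    ----------
    sensorgrams : traces sharing one (ka, kd, Rmax) triple.  Two or more
        concentrations are recommended; single-concentration (or
        dissociation-only) data is accepted but the results flag the
        identifiability problem instead of hiding it.
    """

    def __init__(self, sensorgrams: list[Sensorgram]):
        if not sensorgrams:
            raise ValueError("need at least one sensorgram")
        self.sensorgrams = list(sensorgrams)
        self.concentrations = [s.analyte_conc for s in self.sensorgrams]

    # residuals over log-parameters (enforces positivity); clipped so a wild
    # multi-start step cannot overflow exp()
    def _residuals(self, logp: np.ndarray) -> np.ndarray:
        params = KineticParams(*np.exp(np.clip(logp, -50.0, 50.0)))
        return np.concatenate([
            langmuir_response(s.times, params, s.analyte_conc, s.t_assoc) - s.responses
            for s in self.sensorgrams])

    def _initial_guesses(self, n_starts: int, seed: int | None) -> list[np.ndarray]:
        rmax0 = max(float(np.max(np.abs(s.responses))) for s in self.sensorgrams)
        rmax0 = max(rmax0, 1e-6)
        # kd from the dissociation tail of the highest-signal trace
        s = max(self.sensorgrams, key=lambda s: np.max(np.abs(s.responses)))
        mask = s.times > s.t_assoc
        kd0 = 1e-3
        if mask.sum() >= 3:
            y = s.responses[mask]
            t = s.times[mask] - s.t_assoc
            pos = y > 0.05 * rmax0
            if pos.sum() >= 3:
                slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
                if slope < 0:
                    kd0 = min(max(-slope, 1e-7), 1.0)
        conc = max((c for c in self.concentrations if c > 0), default=1e-9)
        ka0 = kd0 / conc  # guess KD ~ working concentration
        base = np.log([ka0, kd0, rmax0 * 1.2])
        guesses = [base]
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            guesses.append(base + rng.normal(0.0, [1.5, 1.0, 0.3]))
        return guesses

    def fit(self, n_starts: int = 4, seed: int | None = 0) -> "LangmuirResults":
        """Global least squares with multi-start initialization.

        Never raises on non-convergence: the results object carries
        ``converged=False`` with the best parameters found so far.
        """
        best = None
        for x0 in self._initial_guesses(n_starts, seed):
            try:
                sol = least_squares(self._residuals, x0, method="lm",
                                    max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimization starts failed")

        logp = best.x
        params = KineticParams(*np.exp(logp))
        resid = best.fun
        n_obs = resid.size
        dof = max(n_obs - 3, 1)
        sigma2 = float(resid @ resid) / dof
        try:
            J = best.jac
            cov_log = sigma2 * np.linalg.inv(J.T @ J)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se_log = np.full(3, np.nan)
        # delta method: se on linear scale = p * se(log p)
        se = np.exp(logp) * se_log

        flags = []
        positive_concs = [c for c in self.concentrations if c > 0]
        if not positive_concs:
            flags.append("ka unidentifiable: no association-phase signal "
                         "(all analyte concentrations are zero)")
        if len(set(self.concentrations)) < 2:
            flags.append("single-concentration fit: ka/Rmax weakly identified")
        if np.any(~np.isfinite(se_log)) or (np.isfinite(se_log[0]) and se_log[0] > 2.0):
            flags.append("ka poorly determined (log-scale SE > 2)")

        return LangmuirResults(
            model=self,
            params=params,
            bse={"ka": float(se[0]), "kd": float(se[1]), "rmax": float(se[2])},
            residual_norm=float(np.sqrt(best.cost * 2.0)),
            converged=bool(best.success),
            n_obs=n_obs,
            flags=flags,
        )


@dataclass
class LangmuirResults:
    """Fitted rate constants with uncertainties and diagnostics."""

    model: LangmuirModel
    params: KineticParams
    bse: dict[str, float]
    residual_norm: float
    converged: bool
    n_obs: int
    flags: list[str] = field(default_factory=list)

    @property
    def ka(self) -> float:
        return self.params.ka

    @property
    def kd(self) -> float:
        return self.params.kd

    @property
    def KD_nM(self) -> float:
        return self.params.KD_nM

    def predict(self, sensorgram: Sensorgram | None = None,
                times: np.ndarray | None = None,
                conc: float | None = None,
                t_assoc: float | None = None) -> np.ndarray:
        if sensorgram is not None:
            times, conc, t_assoc = sensorgram.times, sensorgram.analyte_conc, sensorgram.t_assoc
        return langmuir_response(times, self.params, conc, t_assoc)

    def summary(self) -> str:
        buf = io.StringIO()
        p, se = self.params, self.bse
        buf.write("1:1 Langmuir global fit\n")
        buf.write("=" * 54 + "\n")
        buf.write(f"{'n traces':<22}{len(self.model.sensorgrams)}\n")
        buf.write(f"{'n observations':<22}{self.n_obs}\n")
        buf.write(f"{'converged':<22}{self.converged}\n")
        buf.write(f"{'residual norm (RU)':<22}{self.residual_norm:.4g}\n")
        buf.write("-" * 54 + "\n")
        buf.write(f"{'parameter':<12}{'estimate':>14}{'std err':>14}\n")
        buf.write(f"{'ka (1/Ms)':<12}{p.ka:>14.4g}{se['ka']:>14.3g}\n")
        buf.write(f"{'kd (1/s)':<12}{p.kd:>14.4g}{se['kd']:>14.3g}\n")
        buf.write(f"{'Rmax (RU)':<12}{p.rmax:>14.4g}{se['rmax']:>14.3g}\n")
        buf.write(f"{'KD (nM)':<12}{p.KD_nM:>14.4g}\n")
        for flag in self.flags:
            buf.write(f"warning: {flag}\n")
        return buf.getvalue()

    def plot(self, ax=None):
        """Overlay data and fitted curves, one colour per concentration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.model.sensorgrams:
            line, = ax.plot(s.times, s.responses, ".", ms=2, alpha=0.5,
                            label=f"{s.analyte_conc * 1e9:.3g} nM")
            ax.plot(s.times, self.predict(s), "-", color=line.get_color())
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        ax.legend(title="analyte", fontsize=8)
        return ax


def fit_kinetics(sensorgrams: list[Sensorgram], n_starts: int = 4,
                 seed: int | None = 0) -> LangmuirResults:
    """Functional wrapper: ``LangmuirModel(sensorgrams).fit()``."""
    return LangmuirModel(sensorgrams).fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# tables & files


def rank_by_affinity(table: pd.DataFrame) -> pd.DataFrame:
    """Append a computed ``KD_nM`` column and sort ascending by it.

    Expects columns ``label``, ``ka``, ``kd``.  The sort is stable with ties
    broken by label, so equal-affinity candidates come out alphabetically.
    """
    required = {"label", "ka", "kd"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    out = table.copy()
    out["KD_nM"] = [kd_from_rates(ka, kd) for ka, kd in zip(out["ka"], out["kd"])]
    out = out.sort_values(["KD_nM", "label"], kind="stable").reset_index(drop=True)
    return out


def load_kinetics_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited rate-constant table with headered columns
    (label, ka, kd[, KD_reported_nM])."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    return df


def load_reference_kinetics() -> pd.DataFrame:
    """The packaged 15-candidate humanized-antibody kinetics table
    (ka, kd and reported KD against immobilized EGFRvIII)."""
    path = Path(__file__).parent / "data" / "table1_kinetics.tsv"
    return load_kinetics_table(path)


def write_sensorgram(sensorgram: Sensorgram, path: str | Path) -> None:
    """Two-column time/response text with the concentration and phase
    boundary in comment headers."""
    with open(path, "w") as fh:
        fh.write(f"# analyte_conc_M\t{sensorgram.analyte_conc:.6e}\n")
        fh.write(f"# t_assoc_s\t{sensorgram.t_assoc:.6f}\n")
        fh.write("# time_s\tresponse_RU\n")
        for t, r in zip(sensorgram.times, sensorgram.responses):
            fh.write(f"{t:.6f}\t{r:.6f}\n")


def read_sensorgram(path: str | Path) -> Sensorgram:
    conc = None
    t_assoc = None
    times, resp = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "analyte_conc_M":
                    conc = float(parts[1])
                elif parts and parts[0] == "t_assoc_s":
                    t_assoc = float(parts[1])
                continue
            t, r = line.split()
            times.append(float(t))
            resp.append(float(r))
    if conc is None or t_assoc is None:
        raise ValueError(f"{path}: missing analyte_conc_M / t_assoc_s headers")
    return Sensorgram(np.array(times), np.array(resp), conc, t_assoc)
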