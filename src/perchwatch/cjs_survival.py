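"""Cormack-Jolly-Seber apparent-survival estimation from monthly encounter
histories.

The likelihood conditions on first release.  For a history with first
encounter at occasion ``f`` and last at ``l`` (0-based), the contribution is

    prod_{t=f}^{l-1} phi_t * (p_{t+1} if seen at t+1 else 1 - p_{t+1})
    * chi_l

with the never-seen-again recursion ``chi_{T-1} = 1`` and
``chi_t = (1 - phi_t) + phi_t * (1 - p_{t+1}) * chi_{t+1}``.

Survival (phi) and detection (p) are logit-linked to design terms drawn from
``{1, season, sex, adult}``.  The season covariate acts on survival through
the interval's *starting* month and on detection through the occasion's own
month (WINTER = Dec/Jan/Feb).  Model comparison uses AICc with effective
sample size equal to the number of usable histories by default.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .detections_io import Age, BirdRecord, Detection, Sex

_LOGIT_CLIP = 35.0
BOUNDARY_LOGIT = 10.0

# MARK .inp group column order
_INP_GROUPS = [(Sex.F, Age.AHY), (Sex.F, Age.HY), (Sex.M, Age.AHY), (Sex.M, Age.HY)]


@dataclass(frozen=True)
class EncounterHistory:
    tag_id: str
    h: tuple[int, ...]           # 0/1 over T occasions
    sex: Sex
    age: Age
    winter: tuple[int, ...]      # per-occasion WINTER indicator (same T)

    def __post_init__(self) -> None:
        if len(self.winter) != len(self.h):
            raise ValueError("winter vector must match history length")
        if 1 not in self.h:
            raise ValueError("history must contain at least one encounter")
        if any(x not in (0, 1) for x in self.h):
            raise ValueError("history entries must be 0/1")

    @property
    def f(self) -> int:
        return self.h.index(1)

    @property
    def last(self) -> int:
        return len(self.h) - 1 - self.h[::-1].index(1)

    @property
    def usable(self) -> bool:
        """Histories first seen at the final occasion carry no information."""
        return self.f < len(self.h) - 1


def month_sequence(start_year: int, start_month: int, n: int) -> list[tuple[int, int]]:
    out = []
    y, m = start_year, start_month
    for _ in range(n):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def is_winter_month(month: int) -> int:
    return int(month in (12, 1, 2))


def build_encounter_histories(
    detections: Sequence[Detection],
    roster: Sequence[BirdRecord],
    start_month: tuple[int, int],
    n_occasions: int = 13,
    cohort_filter: Callable[[BirdRecord], bool] | None = None,
) -> list[EncounterHistory]:
    """Monthly encounter histories: h[t] = 1 iff the bird was detected at
    least once (anywhere) in calendar month t, with the tagging month as the
    release occasion (capture counts as the first encounter).

    Birds whose tagging month falls outside the occasion window are excluded
    with a warning.
    """
    months = month_sequence(start_month[0], start_month[1], n_occasions)
    month_index = {ym: t for t, ym in enumerate(months)}
    winter = tuple(is_winter_month(m) for _, m in months)

    det_months: dict[str, set[int]] = {}
    for d in detections:
        t = month_index.get((d.timestamp.year, d.timestamp.month))
        if t is not None:
            det_months.setdefault(d.tag_id, set()).add(t)

    out: list[EncounterHistory] = []
    for bird in roster:
        if cohort_filter is not None and not cohort_filter(bird):
            continue
        f = month_index.get((bird.tag_date.year, bird.tag_date.month))
        if f is None:
            warnings.warn(
                f"bird {bird.tag_id}: tagging month outside occasion window; excluded"
            )
            continue
        h = [0] * n_occasions
        h[f] = 1
        for t in det_months.get(bird.tag_id, ()):
            if t >= f:
                h[t] = 1
        out.append(
            EncounterHistory(
                tag_id=bird.tag_id, h=tuple(h), sex=bird.sex, age=bird.age,
                winter=winter,
            )
        )
    return out


# ---------------------------------------------------------------------------
# MARK .inp interchange

def write_mark_inp(histories: Sequence[EncounterHistory], target) -> None:
    """Write histories as MARK .inp lines ``<history> g1 g2 g3 g4 ;`` with
    group frequency columns ordered (F-AHY, F-HY, M-AHY, M-HY)."""
    lengths = {len(h.h) for h in histories}
    if len(lengths) > 1:
        raise ValueError("ragged histories: all must share the same T")

    def _write(fh):
        for h in histories:
            try:
                g = _INP_GROUPS.index((h.sex, h.age))
            except ValueError:
                raise ValueError(
                    f"bird {h.tag_id}: sex/age {h.sex.value}/{h.age.value} has no "
                    "inp group column"
                ) from None
            freqs = ["0"] * len(_INP_GROUPS)
            freqs[g] = "1"
            fh.write("".join(str(x) for x in h.h) + " " + " ".join(freqs) + " ;\n")

    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)


def read_mark_inp(source, winter: tuple[int, ...] | None = None) -> list[EncounterHistory]:
    """Parse MARK .inp lines back into histories (inverse of
    :func:`write_mark_inp`; the winter vector is not encoded in .inp, so it
    defaults to all-zero unless supplied)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    out: list[EncounterHistory] = []
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise ValueError(f"inp line {i}: missing terminating ';'")
        parts = line[:-1].split()
        if len(parts) != 1 + len(_INP_GROUPS):
            raise ValueError(f"inp line {i}: expected history + "
                             f"{len(_INP_GROUPS)} group columns")
        hist = tuple(int(c) for c in parts[0])
        w = winter if winter is not None else tuple([0] * len(hist))
        for g, count in enumerate(parts[1:]):
            n = int(count)
            sex, age = _INP_GROUPS[g]
            for k in range(n):
                out.append(
                    EncounterHistory(
                        tag_id=f"inp-{i}-{g}-{k}", h=hist, sex=sex, age=age, winter=w,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Likelihood

def _stack(histories: Sequence[EncounterHistory]):
    H = np.array([h.h for h in histories], dtype=int)
    f = np.array([h.f for h in histories])
    last = np.array([h.last for h in histories])
    return H, f, last


def _core_loglik(H, f, last, phi, p) -> float:
    """phi, p: (n, T-1) arrays; p[:, t] is detection probability at occasion
    t+1.  Returns the summed log-likelihood."""
    n, T = H.shape
    chi = np.ones((n, T))
    for t in range(T - 2, -1, -1):
        chi[:, t] = (1 - phi[:, t]) + phi[:, t] * (1 - p[:, t]) * chi[:, t + 1]
    tt = np.arange(T - 1)
    mask = (tt >= f[:, None]) & (tt < last[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.log(phi) + np.where(H[:, 1:] == 1, np.log(p), np.log1p(-p))
    ll = float(np.where(mask, term, 0.0).sum())
    ll += float(np.log(np.clip(chi[np.arange(n), last], 1e-300, None)).sum())
    return ll


def cjs_loglik(histories: Sequence[EncounterHistory], phi, p) -> float:
    """Log-likelihood at given real-scale parameters.

    ``phi`` and ``p`` may be scalars or (n, T-1) arrays; ``p[:, t]`` applies
    to occasion t+1.  A probability of exactly 0 or 1 that zeroes an observed
    event yields -inf.
    """
    H, f, last = _stack(histories)
    n, T = H.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n, T - 1))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n, T - 1))
    return _core_loglik(H, f, last, phi, p)


# ---------------------------------------------------------------------------
# Model fitting

_VALID_TERMS = {"season", "sex", "adult"}


def _parse_formula(formula: str) -> list[str]:
    body = formula.strip()
    if body.startswith("~"):
        body = body[1:]
    terms = [t.strip() for t in body.split("+") if t.strip()]
    if terms == ["1"]:
        return []
    out = []
    for t in terms:
        if t == "1":
            continue
        if t not in _VALID_TERMS:
            raise ValueError(f"unknown model term {t!r}")
        out.append(t)
    return out


def _covariate_values(h: EncounterHistory, term: str) -> float | None:
    if term == "sex":
        return {Sex.F: 0.0, Sex.M: 1.0}.get(h.sex)
    if term == "adult":
        return {Age.AHY: 1.0, Age.HY: 0.0}.get(h.age)
    raise ValueError(term)


def _design(histories, terms, kind: str) -> tuple[np.ndarray, list[str]]:
    """(n, T-1, k) design tensor on the logit scale.

    ``season`` uses the interval's starting month for phi and the occasion's
    own month (t+1) for p; sex and adult are constant per bird.
    """
    n = len(histories)
    T = len(histories[0].h)
    cols = [np.ones((n, T - 1))]
    names = ["(Intercept)"]
    for term in terms:
        if term == "season":
            w = np.array([h.winter for h in histories], dtype=float)
            col = w[:, :-1] if kind == "phi" else w[:, 1:]
        else:
            vals = np.array([_covariate_values(h, term) for h in histories],
                            dtype=float)
            col = np.repeat(vals[:, None], T - 1, axis=1)
        cols.append(col)
        names.append(term)
    return np.stack(cols, axis=-1), names


@dataclass
class CJSFit:
    phi_formula: str
    p_formula: str
    beta: np.ndarray
    se: np.ndarray
    coef_names: list[str]
    logLik: float
    K: int
    AICc: float
    ess: int
    converged: bool
    boundary: bool
    n_histories: int
    vcov: np.ndarray | None = None
    _split: int = field(default=0, repr=False)

    @property
    def model_label(self) -> str:
        return f"Phi({self.phi_formula}) p({self.p_formula})"

    def _predict(self, kind: str, covariates: dict) -> tuple[float, float]:
        names = [n for n in self.coef_names if n.startswith(f"{kind}:")]
        offset = 0 if kind == "phi" else self._split
        x = np.zeros(len(names))
        for i, full in enumerate(names):
            term = full.split(":", 1)[1]
            x[i] = 1.0 if term == "(Intercept)" else float(covariates.get(term, 0.0))
        b = self.beta[offset:offset + len(names)]
        eta = float(x @ b)
        prob = float(expit(eta))
        se = float("nan")
        if self.vcov is not None:
            v = self.vcov[offset:offset + len(names), offset:offset + len(names)]
            eta_se = float(np.sqrt(max(x @ v @ x, 0.0)))
            se = prob * (1 - prob) * eta_se  # delta method
        return prob, se

    def predict_phi(self, covariates: dict | None = None) -> tuple[float, float]:
        """Real-scale survival (and delta-method SE) at a covariate setting,
        e.g. ``predict_phi({"adult": 1, "season": 0})``."""
        return self._predict("phi", covariates or {})

    def predict_p(self, covariates: dict | None = None) -> tuple[float, float]:
        return self._predict("p", covariates or {})


def aicc(logLik: float, K: int, ess: float) -> float:
    """AICc = -2 logLik + 2K + 2K(K+1)/(ess - K - 1)."""
    if ess <= K + 1:
        raise ValueError("effective sample size must exceed K + 1")
    return -2.0 * logLik + 2.0 * K + 2.0 * K * (K + 1) / (ess - K - 1)


def _numeric_hessian(fun, x, h=1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_cjs(
    histories: Sequence[EncounterHistory],
    phi_formula: str = "~1",
    p_formula: str = "~1",
    ess_mode: str = "releases",
    gtol: float = 1e-8,
) -> CJSFit:
    """Maximum-likelihood CJS fit with logit-linked phi and p.

    Coefficients start at zero (probabilities 0.5) and are optimized with
    L-BFGS-B; standard errors come from the numerically differentiated
    Hessian at the optimum.  Birds with UNKNOWN sex/age are excluded (with a
    warning) whenever a formula references sex or adult.  ``ess_mode`` is one
    of ``releases`` (number of usable histories, default), ``detections``
    (total encounters), or ``intervals`` (bird-intervals at risk).
    """
    phi_terms = _parse_formula(phi_formula)
    p_terms = _parse_formula(p_formula)
    needed = set(phi_terms) | set(p_terms)

    usable = [h for h in histories if h.usable]
    if needed & {"sex", "adult"}:
        kept = [
            h for h in usable
            if ("sex" not in needed or h.sex is not Sex.UNKNOWN)
            and ("adult" not in needed or h.age is not Age.UNKNOWN)
        ]
        if len(kept) < len(usable):
            warnings.warn(
                f"excluded {len(usable) - len(kept)} histories with UNKNOWN "
                "sex/age from covariate model"
            )
        usable = kept
    if not usable:
        raise ValueError("no usable encounter histories")

    H, f, last = _stack(usable)
    X_phi, phi_names = _design(usable, phi_terms, "phi")
    X_p, p_names = _design(usable, p_terms, "p")
    k_phi = X_phi.shape[-1]
    k_p = X_p.shape[-1]
    K = k_phi + k_p

    def negloglik(beta: np.ndarray) -> float:
        eta_phi = np.clip(X_phi @ beta[:k_phi], -_LOGIT_CLIP, _LOGIT_CLIP)
        eta_p = np.clip(X_p @ beta[k_phi:], -_LOGIT_CLIP, _LOGIT_CLIP)
        return -_core_loglik(H, f, last, expit(eta_phi), expit(eta_p))

    res = optimize.minimize(
        negloglik,
        np.zeros(K),
        method="L-BFGS-B",
        options={"gtol": gtol, "ftol": 1e-12, "maxiter": 500},
    )
    beta = res.x
    logLik = -float(res.fun)

    hess = _numeric_hessian(negloglik, beta)
    se = np.full(K, np.nan)
    vcov = None
    try:
        vcov = np.linalg.inv(hess)
        diag = np.diag(vcov)
        if np.all(diag > 0):
            se = np.sqrt(diag)
        else:
            vcov = None
    except np.linalg.LinAlgError:
        pass

    eta_all = np.concatenate(
        [(X_phi @ beta[:k_phi]).ravel(), (X_p @ beta[k_phi:]).ravel()]
    )
    boundary = bool(np.any(np.abs(eta_all) > BOUNDARY_LOGIT))

    if ess_mode == "releases":
        ess = len(usable)
    elif ess_mode == "detections":
        ess = int(H.sum())
    elif ess_mode == "intervals":
        ess = int(np.sum(len(usable[0].h) - 1 - f))
    else:
        raise ValueError(f"unknown ess_mode {ess_mode!r}")

    return CJSFit(
        phi_formula=phi_formula,
        p_formula=p_formula,
        beta=beta,
        se=se,
        coef_names=[f"phi:{n}" for n in phi_names] + [f"p:{n}" for n in p_names],
        logLik=logLik,
        K=K,
        AICc=aicc(logLik, K, ess),
        ess=ess,
        converged=bool(res.success),
        boundary=boundary,
        n_histories=len(usable),
        vcov=vcov,
        _split=k_phi,
    )


def _selection_table(fits: Sequence[CJSFit]) -> list[dict]:
    rows = sorted(fits, key=lambda fit: fit.AICc)
    best = rows[0].AICc
    deltas = [fit.AICc - best for fit in rows]
    raw = np.exp(-0.5 * np.asarray(deltas))
    weights = raw / raw.sum()
    return [
        {
            "model": fit.model_label,
            "phi_formula": fit.phi_formula,
            "p_formula": fit.p_formula,
            "Npar": fit.K,
            "AICc": fit.AICc,
            "dAICc": delta,
            "weight": float(w),
            "strong_support": delta < 2.0,
            "fit": fit,
        }
        for fit, delta, w in zip(rows, deltas, weights)
    ]


def model_selection_two_step(
    histories: Sequence[EncounterHistory], ess_mode: str = "releases"
) -> tuple[list[dict], list[dict]]:
    """Two-step AICc model selection.

    Step 1 varies the detection model under a full survival model
    (``Phi(~season+sex+adult)``) over ``p in {~1, ~adult, ~sex, ~season}``
    plus the full null ``Phi(~1) p(~1)``.  Step 2 fixes p at the step-1
    winner and varies ``Phi in {~1, ~adult, ~sex, ~season}``.  Non-convergent
    members are excluded with a warning.  Each table carries dAICc, Akaike
    weights, and a strong-support flag (dAICc < 2).
    """
    def _try_fit(phi_f, p_f):
        fit = fit_cjs(histories, phi_f, p_f, ess_mode=ess_mode)
        if not fit.converged:
            warnings.warn(f"model {fit.model_label} did not converge; excluded")
            return None
        return fit

    step1_specs = [("~season+sex+adult", p) for p in ("~1", "~adult", "~sex", "~season")]
    step1_specs.append(("~1", "~1"))
    step1 = [f for f in (_try_fit(*s) for s in step1_specs) if f is not None]
    if not step1:
        raise RuntimeError("no step-1 model converged")
    table1 = _selection_table(step1)
    best_p = table1[0]["p_formula"]

    step2_specs = [(phi, best_p) for phi in ("~1", "~adult", "~sex", "~season")]
    step2 = [f for f in (_try_fit(*s) for s in step2_specs) if f is not None]
    table2 = _selection_table(step2)
    return table1, table2


def annual_survival(phi_monthly: float) -> float:
    """Annualize a monthly apparent-survival probability (12th power)."""
    if not 0.0 <= phi_monthly <= 1.0:
        raise ValueError("phi_monthly must be in [0, 1]")
    return phi_monthly ** 12


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]
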