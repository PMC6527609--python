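"""Closed-form isoform-proportion model for an exon-skipping splice QTL
whose mis-spliced product is degraded by nonsense-mediated decay (NMD).

The model describes a biallelic locus with a reference ("C") and a minor
("a") haplotype.  Each haplotype transcribes a mix of normally spliced and
mis-spliced isoforms; normal isoforms survive NMD with probability 1,
mis-spliced isoforms with probability ``p_m``.  Three observable ratios
constrain the system:

* ``k_hom``  — surviving normal : surviving mis-spliced in reference
  homozygotes;
* ``k_het``  — combined surviving normal : combined surviving mis-spliced in
  heterozygotes;
* ``r``      — ratio of total surviving output, reference vs minor haplotype.

Writing ``u = (1 - n_c) * p_m`` and ``v = (1 - n_a) * p_m`` (the surviving
mis-spliced fractions per haplotype) makes the system linear and it is
solved by elimination; a numeric root-finder on the original nonlinear
system is available as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InfeasibleInputsError, SingularModelError

_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class IsoformModelInputs:
    """Observable ratios constraining the isoform model.

    Defaults correspond to a locus where the normal isoform is 100x the
    surviving mis-spliced one in reference homozygotes, 25x in
    heterozygotes, and the reference haplotype yields 3x the surviving
    output of the minor haplotype.
    """

    k_hom: float = 100.0
    k_het: float = 25.0
    r: float = 3.0
    p_n: float = 1.0

    def __post_init__(self) -> None:
        if not self.k_hom > 1:
            raise ConfigurationError(f"k_hom must exceed 1, got {self.k_hom}")
        if not self.k_het > 1:
            raise ConfigurationError(f"k_het must exceed 1, got {self.k_het}")
        if not self.r > 0:
            raise ConfigurationError(f"r must be positive, got {self.r}")
        if self.p_n != 1.0:
            raise ConfigurationError("p_n is fixed to 1 (normal isoforms escape NMD)")


@dataclass(frozen=True)
class IsoformModelSolution:
    n_c: float  # fraction of reference-haplotype transcripts spliced normally
    n_a: float  # same for the minor haplotype
    p_m: float  # NMD survival probability of mis-spliced transcripts
    u: float    # (1 - n_c) * p_m
    v: float    # (1 - n_a) * p_m


@dataclass(frozen=True)
class ImpliedFractions:
    cc_mis_pct: float       # surviving mis-spliced % in reference homozygotes
    het_mis_pct: float      # surviving mis-spliced % in heterozygotes
    hap_ratio: float        # surviving reference/minor haplotype total ratio
    nmd_degraded_pct: float  # 100 * (1 - p_m)


def solve_isoform_model(inputs: IsoformModelInputs) -> IsoformModelSolution:
    """Solve the three-constraint system exactly.

    Elimination: with ``n_c = k_hom * u`` and ``n_a = k_het*(u+v) - k_hom*u``
    the third constraint fixes ``v = gamma * u`` with

        gamma = (1 + k_hom + r*(k_hom - k_het)) / (r * (k_het + 1))

    and the closure ``u*(1-n_a) = v*(1-n_c)`` (both haplotypes share the
    same ``p_m``) then yields ``u = (gamma-1) / ((1+gamma)*(k_hom-k_het))``.
    """
    kh, kt, r = inputs.k_hom, inputs.k_het, inputs.r
    denom_gamma = r * (kt + 1.0)
    gamma = (1.0 + kh + r * (kh - kt)) / denom_gamma

    if abs(kh - kt) < 1e-12 or abs(gamma - 1.0) < 1e-12:
        raise SingularModelError(
            "degenerate inputs: the (u, v) elimination has no unique solution "
            f"(k_hom={kh}, k_het={kt}, r={r})"
        )

    u = (gamma - 1.0) / ((1.0 + gamma) * (kh - kt))
    v = gamma * u
    n_c = kh * u
    n_a = kt * (u + v) - n_c

    for name, val in (("n_c", n_c), ("n_a", n_a)):
        if not 0.0 < val < 1.0:
            raise InfeasibleInputsError(f"{name}={val:.6g} outside (0, 1); inputs infeasible")
    p_m = u / (1.0 - n_c)
    if not 0.0 < p_m < 1.0:
        raise InfeasibleInputsError(f"p_m={p_m:.6g} outside (0, 1); inputs infeasible")

    sol = IsoformModelSolution(n_c=n_c, n_a=n_a, p_m=p_m, u=u, v=v)
    res = residuals(sol, inputs)
    scales = (max(1.0, abs(kh * u)), max(1.0, abs(kt * (u + v))),
              max(1.0, abs(r * (n_a + v))))
    if max(abs(x) / s for x, s in zip(res, scales)) > _RESIDUAL_TOL:
        raise SingularModelError(f"solution residuals {res} exceed tolerance")
    return sol


def residuals(sol: IsoformModelSolution, inputs: IsoformModelInputs) -> tuple[float, float, float]:
    """Residuals of the three original constraints at a candidate solution."""
    n_c, n_a, p_m = sol.n_c, sol.n_a, sol.p_m
    u = (1.0 - n_c) * p_m
    v = (1.0 - n_a) * p_m
    return (
        n_c - inputs.k_hom * u,
        (n_c + n_a) - inputs.k_het * (u + v),
        (n_c + u) - inputs.r * (n_a + v),
    )


def solve_isoform_model_numeric(
    inputs: IsoformModelInputs, x0: tuple[float, float, float] = (0.8, 0.3, 0.1)
) -> IsoformModelSolution:
    """Root-find the original nonlinear system; cross-check for the exact path."""
    from scipy.optimize import fsolve

    def system(x):
        cand = IsoformModelSolution(n_c=x[0], n_a=x[1], p_m=x[2],
                                    u=(1 - x[0]) * x[2], v=(1 - x[1]) * x[2])
        return residuals(cand, inputs)

    root, info, ier, msg = fsolve(system, x0, full_output=True)
    if ier != 1:
        raise SingularModelError(f"numeric solver failed: {msg}")
    n_c, n_a, p_m = map(float, root)
    return IsoformModelSolution(n_c=n_c, n_a=n_a, p_m=p_m,
                                u=(1 - n_c) * p_m, v=(1 - n_a) * p_m)


def implied_fractions(sol: IsoformModelSolution, inputs: IsoformModelInputs) -> ImpliedFractions:
    """Observable steady-state fractions implied by a feasible solution.

    Algebraically ``cc_mis_pct == 100/(k_hom+1)`` and
    ``het_mis_pct == 100/(k_het+1)`` for any feasible inputs.
    """
    u, v, n_c, n_a = sol.u, sol.v, sol.n_c, sol.n_a
    return ImpliedFractions(
        cc_mis_pct=100.0 * u / (n_c + u),
        het_mis_pct=100.0 * (u + v) / (n_c + n_a + u + v),
        hap_ratio=(n_c + u) / (n_a + v),
        nmd_degraded_pct=100.0 * (1.0 - sol.p_m),
    )


def sensitivity_scan(
    inputs: IsoformModelInputs,
    ranges: dict[str, tuple[float, float]],
    steps: int,
):
    """Solve the model over a grid of input perturbations.

    ``ranges`` maps parameter names (``k_hom``, ``k_het``, ``r``) to
    inclusive intervals scanned with ``steps`` points each (full cartesian
    grid).  Infeasible or singular cells are flagged, not raised.
    """
    import itertools

    import pandas as pd

    if steps < 1 or not ranges:
        raise ConfigurationError("sensitivity_scan requires >=1 step and a nonempty range map")
    for key in ranges:
        if key not in ("k_hom", "k_het", "r"):
            raise ConfigurationError(f"unknown scan parameter {key!r}")

    axes = {k: np.linspace(lo, hi, steps) for k, (lo, hi) in ranges.items()}
    rows = []
    for combo in itertools.product(*axes.values()):
        params = {"k_hom": inputs.k_hom, "k_het": inputs.k_het, "r": inputs.r}
        params.update(dict(zip(axes.keys(), combo)))
        row = dict(params)
        try:
            sol = solve_isoform_model(IsoformModelInputs(**params))
            frac = implied_fractions(sol, IsoformModelInputs(**params))
            row.update(n_c=sol.n_c, n_a=sol.n_a, p_m=sol.p_m,
                       nmd_degraded_pct=frac.nmd_degraded_pct, feasible=True)
        except (InfeasibleInputsError, SingularModelError, ConfigurationError):
            row.update(n_c=np.nan, n_a=np.nan, p_m=np.nan,
                       nmd_degraded_pct=np.nan, feasible=False)
        rows.append(row)
    return pd.DataFrame(rows)
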