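"""Domain types and promoter switching-rate functions for the three-gene
BCL6-IRF4-BLIMP1 network.

Each gene carries a two-state promoter switching on at rate ``k_on`` and off
at rate ``k_off``.  Both rates respond to regulator proteins and to the
stimuli BCR/CD40 through the interaction function

    Phi_i(P, Q) = prod_s (1 + e^{theta_si} Q_s/H_si) / (1 + Q_s/H_si)
                * prod_j (1 + e^{theta_ji} (x_j/H_ji)^gamma) / (1 + (x_j/H_ji)^gamma)

where ``x_j`` is the abundance of regulator protein j on the interaction
scale (fraction of its theoretical maximum, see
:meth:`NetworkModel.fractional_protein`), ``theta`` encodes sign and strength
of an edge, ``H`` its threshold and ``gamma`` the Hill exponent (stimulus
factors use exponent 1).  The rates are sigmoid in Phi:

    k_on  = k_on^min  + k_on^max  * (beta_on  Phi_on)  / (1 + beta_on  Phi_on)
    k_off = k_off^min + k_off^max * (beta_off Phi_off) / (1 + beta_off Phi_off)

with Phi_off evaluated under negated theta values.  The per-gene scaling
constants beta are calibrated at model initialisation so that the rates equal
their prescribed initial values at the initial-rate steady state (promoter
occupancy E_ref = k_on,init/(k_on,init + k_off,init), proteins at the
corresponding steady level, stimuli off).  Calibrating at that reference
state -- rather than at zero protein -- is what turns the very large printed
interaction strengths (|theta| up to 200, entering as e^theta) into effective
Hill-type responses around the operating point instead of constitutive
switches.

All internal Phi arithmetic is done in log space so that factors such as
e^{500} * r remain finite for any parameter set within the documented sweep
ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy.special import expit

GENES: Tuple[str, str, str] = ("BCL6", "IRF4", "BLIMP1")
STIMULI: Tuple[str, str] = ("BCR", "CD40")
#: regulators in fixed order: the three proteins then the two stimuli
REGULATORS: Tuple[str, ...] = GENES + STIMULI

#: index map (1-based in the source tables, 0-based here)
GENE_INDEX: Dict[str, int] = {g: i for i, g in enumerate(GENES)}

#: edges that are absent from the network topology: no influence of BCL6 or
#: BLIMP1 on IRF4, no BLIMP1 self-interaction, BCR acts only on BCL6 and
#: CD40 only on IRF4.
STRUCTURAL_ZEROS: Tuple[Tuple[str, str], ...] = (
    ("BCL6", "IRF4"),
    ("BLIMP1", "IRF4"),
    ("BLIMP1", "BLIMP1"),
    ("BCR", "IRF4"),
    ("BCR", "BLIMP1"),
    ("CD40", "BCL6"),
    ("CD40", "BLIMP1"),
)


#: default bounds on the promoter switching rates.  The source tables print
#: the initial rates but not their bounds, so these are calibrated constants
#: of this implementation, chosen once so that the shipped parameter tables
#: reproduce the reported qualitative dynamics (two stimulus-separated steady
#: states for version I, loss of the second state when k_on,init,IRF4 is an
#: order of magnitude larger, and the GC -> PB_PC expression switch of
#: version III):
#:
#: * each gene's k_on floor is half its initial rate
#:   (kon_min = DEFAULT_FLOOR_FRACTION * kon_init) -- a basal activation
#:   level that prevents the activation rate from collapsing far below its
#:   calibrated operating point;
#: * the k_off floor is the absolute DEFAULT_KOFF_MIN, letting strongly
#:   activated genes hold long promoter on-times;
#: * both rates saturate at 2/h (GeneParameters defaults kon_max, koff_max).
DEFAULT_FLOOR_FRACTION = 0.5
DEFAULT_KOFF_MIN = 0.02


class CalibrationError(ValueError):
    """Raised when beta cannot be calibrated or has not been calibrated."""


class InvalidThresholdError(ValueError):
    """Raised when an interaction threshold H is not strictly positive."""


class DegenerateRatesError(ValueError):
    """Raised when k_on = k_off = 0 makes the promoter process undefined."""


@dataclass(frozen=True)
class GeneParameters:
    """Kinetic constants of a single gene.

    Rates are per hour; ``s0`` is mRNA/h while the promoter is on, ``s1``
    protein per mRNA per hour.  ``kon_init``/``koff_init`` are the switching
    rates the gene must exhibit at the calibration reference state;
    ``beta_on``/``beta_off`` are the calibrated scalings (``None`` until
    :func:`calibrate_beta` or :meth:`NetworkModel.calibrate` has run).
    """

    gene_id: str
    s0: float
    d0: float
    s1: float
    d1: float
    kon_init: float
    koff_init: float
    kon_min: float = 0.0
    kon_max: float = 2.0
    koff_min: float = 0.0
    koff_max: float = 2.0
    beta_on: float | None = field(default=None, compare=False)
    beta_off: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.gene_id not in GENES:
            raise ValueError(f"unknown gene_id {self.gene_id!r}; expected one of {GENES}")
        for name in ("s0", "d0", "s1", "d1", "kon_init", "koff_init", "kon_max", "koff_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.gene_id}: {name} must be strictly positive")
        for name in ("kon_min", "koff_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene_id}: {name} must be >= 0")
        if not (self.kon_min < self.kon_init < self.kon_min + self.kon_max):
            raise CalibrationError(
                f"{self.gene_id}: kon_init={self.kon_init} outside the open interval "
                f"({self.kon_min}, {self.kon_min + self.kon_max}) required for calibration"
            )
        if not (self.koff_min < self.koff_init < self.koff_min + self.koff_max):
            raise CalibrationError(
                f"{self.gene_id}: koff_init={self.koff_init} outside the open interval "
                f"({self.koff_min}, {self.koff_min + self.koff_max}) required for calibration"
            )
        for name in ("beta_on", "beta_off"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{self.gene_id}: {name} must be >= 0 once calibrated")

    @property
    def mrna_max(self) -> float:
        """Theoretical maximum mean mRNA level, s0/d0 (promoter always on)."""
        return self.s0 / self.d0

    @property
    def protein_max(self) -> float:
        """Theoretical maximum mean protein level, s0*s1/(d0*d1)."""
        return self.s0 * self.s1 / (self.d0 * self.d1)

    @property
    def calibrated(self) -> bool:
        return self.beta_on is not None and self.beta_off is not None


@dataclass(frozen=True)
class InteractionParams:
    """Interaction strengths ``theta`` and thresholds ``H`` over
    (regulator | stimulus) x target gene, plus the Hill exponent ``gamma``.

    Keys are ``(regulator, target)`` name pairs with regulator in
    ``REGULATORS`` and target in ``GENES``.  Pairs that are absent from the
    network topology must carry theta = 0 (their H is conventionally 1).
    """

    theta: Mapping[Tuple[str, str], float]
    H: Mapping[Tuple[str, str], float]
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be strictly positive")
        for (w, i), h in self.H.items():
            self._check_pair(w, i)
            if h <= 0:
                raise InvalidThresholdError(f"H({w},{i}) = {h} must be strictly positive")
        for (w, i) in self.theta:
            self._check_pair(w, i)
        for pair in STRUCTURAL_ZEROS:
            if self.theta.get(pair, 0.0) != 0.0:
                raise ValueError(
                    f"theta{pair} = {self.theta[pair]} but this edge is absent from "
                    "the network topology and must be 0"
                )

    @staticmethod
    def _check_pair(w: str, i: str) -> None:
        if w not in REGULATORS:
            raise ValueError(f"unknown regulator {w!r}")
        if i not in GENES:
            raise ValueError(f"unknown target gene {i!r}")

    def theta_matrix(self) -> np.ndarray:
        """theta as a (5 regulators x 3 targets) array in REGULATORS order."""
        out = np.zeros((len(REGULATORS), len(GENES)))
        for (w, i), v in self.theta.items():
            out[REGULATORS.index(w), GENE_INDEX[i]] = v
        return out

    def h_matrix(self) -> np.ndarray:
        """H as a (5 x 3) array; unspecified pairs default to 1."""
        out = np.ones((len(REGULATORS), len(GENES)))
        for (w, i), v in self.H.items():
            out[REGULATORS.index(w), GENE_INDEX[i]] = v
        return out


def _log_phi_matrix(
    x: np.ndarray,
    q: np.ndarray,
    theta: np.ndarray,
    h: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """log Phi for all three targets at once.

    Parameters
    ----------
    x : (..., 3) regulator protein abundances on the interaction scale
    q : (2,) stimulus intensities (BCR, CD40)
    theta, h : (5, 3) matrices in REGULATORS x GENES order
    gamma : Hill exponent for the protein factors (stimuli use exponent 1)

    Returns ``log Phi`` with shape ``(..., 3)``.  Each factor
    (1 + e^theta r)/(1 + r) is evaluated as
    ``logaddexp(0, theta + log r) - log1p(r)`` so that arbitrarily large
    ``e^theta`` never overflow.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(GENES):
        raise ValueError("x must have shape (n, 3)")
    if np.any(x < 0):
        raise ValueError("protein levels must be >= 0")
    if np.any(q < 0):
        raise ValueError("stimulus intensities must be >= 0")
    with np.errstate(divide="ignore"):  # log(0) -> -inf is the correct limit
        log_r_prot = gamma * np.log(x[:, :, None] / h[None, :3, :])  # (n, 3reg, 3tgt)
        log_r_stim = np.log(q[:, None] / h[3:, :])  # (2, 3tgt)
    # each factor: log[(1 + e^theta r) / (1 + r)] via logaddexp, overflow-free
    log_fac_p = np.logaddexp(0.0, theta[None, :3, :] + log_r_prot) - np.logaddexp(0.0, log_r_prot)
    log_fac_s = np.logaddexp(0.0, theta[3:, :] + log_r_stim) - np.logaddexp(0.0, log_r_stim)
    return log_fac_p.sum(axis=1) + log_fac_s.sum(axis=0)[None, :]


def compute_phi(
    P,
    Q: Mapping[str, float],
    target: str,
    interactions: InteractionParams,
    *,
    negate: bool = False,
) -> float:
    """Interaction function Phi for one target gene.

    ``P`` is the length-3 vector of regulator abundances on the interaction
    scale (see :meth:`NetworkModel.fractional_protein`; the formula itself is
    scale-agnostic), ``Q`` maps stimulus names to intensities.  With
    ``negate=True`` every theta is sign-flipped, giving the Phi that drives
    ``k_off``.
    """
    theta = interactions.theta_matrix()
    if negate:
        theta = -theta
    h = interactions.h_matrix()
    q = np.array([float(Q.get(s, 0.0)) for s in STIMULI])
    x = np.atleast_2d(np.asarray(P, dtype=float))
    log_phi = _log_phi_matrix(x, q, theta, h, interactions.gamma)
    return float(np.exp(log_phi[0, GENE_INDEX[target]]))


def _rate_from_phi(phi: float, beta: float | None, r_min: float, r_max: float, which: str) -> float:
    if beta is None:
        raise CalibrationError(f"beta_{which} has not been calibrated; call calibrate_beta first")
    if beta == 0.0 or phi == 0.0:
        return r_min
    sig = expit(np.log(beta) + np.log(phi))  # b*phi/(1+b*phi), overflow-safe
    return r_min + r_max * float(sig)


def compute_kon(phi: float, g: GeneParameters) -> float:
    """k_on from an already-evaluated Phi (monotone increasing in Phi)."""
    if phi < 0:
        raise ValueError("Phi must be >= 0")
    return _rate_from_phi(phi, g.beta_on, g.kon_min, g.kon_max, "on")


def compute_koff(
    P,
    Q: Mapping[str, float],
    target: str,
    interactions: InteractionParams,
    g: GeneParameters,
) -> float:
    """k_off for ``target``: same sigmoid form as k_on with Phi evaluated
    under negated theta values and the (koff_min, koff_max, beta_off) triple."""
    phi = compute_phi(P, Q, target, interactions, negate=True)
    return _rate_from_phi(phi, g.beta_off, g.koff_min, g.koff_max, "off")


def calibrate_beta(
    g: GeneParameters,
    phi_on_ref: float = 1.0,
    phi_off_ref: float = 1.0,
    *,
    log_refs: Tuple[float, float] | None = None,
) -> GeneParameters:
    """Solve for beta_on and beta_off such that the rates equal
    kon_init/koff_init when Phi takes its reference value.

    With ``phi_*_ref = 1`` (zero proteins, zero stimuli) this is the
    closed-form inverse  beta = (k_init - k_min) / (k_max + k_min - k_init).
    :meth:`NetworkModel.calibrate` passes the log Phi values of the
    initial-rate steady state via ``log_refs`` (overflow-safe for extreme
    theta).
    """
    if log_refs is not None:
        log_on, log_off = log_refs
    else:
        if phi_on_ref <= 0 or phi_off_ref <= 0:
            raise CalibrationError("reference Phi values must be strictly positive")
        log_on, log_off = np.log(phi_on_ref), np.log(phi_off_ref)
    b_on = (g.kon_init - g.kon_min) / (g.kon_min + g.kon_max - g.kon_init)
    b_off = (g.koff_init - g.koff_min) / (g.koff_min + g.koff_max - g.koff_init)
    with np.errstate(divide="ignore"):
        beta_on = float(np.exp(np.log(b_on) - log_on)) if b_on > 0 else 0.0
        beta_off = float(np.exp(np.log(b_off) - log_off)) if b_off > 0 else 0.0
    return replace(g, beta_on=beta_on, beta_off=beta_off)


@dataclass(frozen=True)
class NetworkModel:
    """The full three-gene network: per-gene kinetics plus interactions.

    Gene order is fixed as (BCL6, IRF4, BLIMP1), matching the 1/2/3 index
    convention of the parameter tables.
    """

    genes: Tuple[GeneParameters, GeneParameters, GeneParameters]
    interactions: InteractionParams

    def __post_init__(self) -> None:
        ids = tuple(g.gene_id for g in self.genes)
        if ids != GENES:
            raise ValueError(f"genes must be ordered {GENES}, got {ids}")

    def gene(self, gene_id: str) -> GeneParameters:
        return self.genes[GENE_INDEX[gene_id]]

    # -- vectors over genes, in fixed order ---------------------------------
    def _vec(self, attr: str) -> np.ndarray:
        return np.array([getattr(g, attr) for g in self.genes], dtype=float)

    @property
    def protein_max(self) -> np.ndarray:
        return np.array([g.protein_max for g in self.genes])

    def fractional_protein(self, P) -> np.ndarray:
        """Protein abundance on the interaction scale: P_j / P_j^max with
        P_j^max = s0*s1/(d0*d1).  At steady state this equals the mean
        promoter occupancy of gene j, which ties the interaction thresholds
        H to the (0, 1) occupancy scale."""
        return np.asarray(P, dtype=float) / self.protein_max

    def reference_state(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(E_ref, M_ref, P_ref): the initial-rate steady state at which beta
        is calibrated.  E_ref = kon_init/(kon_init+koff_init), M and P at the
        matching deterministic steady levels, stimuli off."""
        e = self._vec("kon_init") / (self._vec("kon_init") + self._vec("koff_init"))
        m = self._vec("s0") * e / self._vec("d0")
        p = self._vec("s1") * m / self._vec("d1")
        return e, m, p

    def calibrate(self) -> "NetworkModel":
        """Return a copy whose genes carry beta values such that every gene
        exhibits exactly (kon_init, koff_init) at the reference state."""
        _, _, p_ref = self.reference_state()
        x_ref = self.fractional_protein(p_ref)[None, :]
        theta = self.interactions.theta_matrix()
        h = self.interactions.h_matrix()
        q0 = np.zeros(len(STIMULI))
        log_on = _log_phi_matrix(x_ref, q0, theta, h, self.interactions.gamma)[0]
        log_off = _log_phi_matrix(x_ref, q0, -theta, h, self.interactions.gamma)[0]
        new_genes = [
            calibrate_beta(g, log_refs=(log_on[i], log_off[i]))
            for i, g in enumerate(self.genes)
        ]
        return replace(self, genes=tuple(new_genes))

    @property
    def calibrated(self) -> bool:
        return all(g.calibrated for g in self.genes)

    def rates(self, P, Q: Mapping[str, float]) -> Tuple[np.ndarray, np.ndarray]:
        """(k_on, k_off) for all three genes at raw protein levels ``P``
        (molecules) and stimulus intensities ``Q``.  Convenience wrapper
        around the compiled fast path."""
        kon, koff = self.compile().rates(
            self.fractional_protein(P)[None, :],
            np.array([float(Q.get(s, 0.0)) for s in STIMULI]),
        )
        return kon[0], koff[0]

    def compile(self) -> "CompiledNetwork":
        return CompiledNetwork.from_model(self)

    def with_overrides(self, overrides: Mapping[str, float]) -> "NetworkModel":
        """New (uncalibrated-beta) model with named parameters replaced.

        Accepted keys: ``theta.<regulator>.<target>``, ``H.<regulator>.<target>``,
        and per-gene kinetic fields ``<field>.<gene>`` with field one of
        s0, d0, s1, d1, kon_init, koff_init, kon_min, kon_max, koff_min,
        koff_max (e.g. ``s0.IRF4``).
        """
        theta = dict(self.interactions.theta)
        h = dict(self.interactions.H)
        gene_changes: Dict[str, Dict[str, float]] = {gid: {} for gid in GENES}
        for key, value in overrides.items():
            parts = key.split(".")
            if len(parts) == 3 and parts[0] in ("theta", "H"):
                _, w, i = parts
                try:
                    InteractionParams._check_pair(w, i)
                except ValueError as exc:
                    raise KeyError(str(exc)) from exc
                if parts[0] == "theta":
                    theta[(w, i)] = float(value)
                else:
                    h[(w, i)] = float(value)
            elif len(parts) == 2 and parts[1] in GENES:
                fld, gid = parts
                if fld not in (
                    "s0", "d0", "s1", "d1", "kon_init", "koff_init",
                    "kon_min", "kon_max", "koff_min", "koff_max",
                ):
                    raise KeyError(f"unknown gene field in override {key!r}")
                gene_changes[gid][fld] = float(value)
            else:
                raise KeyError(f"unknown parameter name {key!r}")
        inter = InteractionParams(theta=theta, H=h, gamma=self.interactions.gamma)
        new_genes = tuple(
            replace(self.gene(gid), beta_on=None, beta_off=None, **gene_changes[gid])
            for gid in GENES
        )
        return NetworkModel(genes=new_genes, interactions=inter)


def apply_rate_floors(
    model: NetworkModel,
    fraction: float = DEFAULT_FLOOR_FRACTION,
    koff_min: float = DEFAULT_KOFF_MIN,
) -> NetworkModel:
    """Apply the default floor policy: kon_min = ``fraction`` * kon_init per
    gene and the absolute ``koff_min`` (betas are cleared; re-calibrate
    afterwards).

    Call this again after perturbing a ``kon_init`` so the floor tracks the
    new initial rate.
    """
    if not 0 <= fraction < 1:
        raise ValueError("floor fraction must lie in [0, 1)")
    overrides = {}
    for g in model.genes:
        overrides[f"kon_min.{g.gene_id}"] = fraction * g.kon_init
        overrides[f"koff_min.{g.gene_id}"] = koff_min
    return model.with_overrides(overrides)


class CompiledNetwork:
    """Plain-array view of a calibrated :class:`NetworkModel` used by the
    simulation and reduction code paths.  Rates are computed in log space for
    whole batches of cells at once."""

    __slots__ = (
        "s0", "d0", "s1", "d1", "kon_min", "kon_max", "koff_min", "koff_max",
        "log_beta_on", "log_beta_off", "theta", "h", "gamma", "protein_max",
    )

    @classmethod
    def from_model(cls, model: NetworkModel) -> "CompiledNetwork":
        if not model.calibrated:
            raise CalibrationError(
                "NetworkModel must be calibrated (call .calibrate()) before compiling"
            )
        self = cls()
        for attr in ("s0", "d0", "s1", "d1", "kon_min", "kon_max", "koff_min", "koff_max"):
            setattr(self, attr, model._vec(attr))
        with np.errstate(divide="ignore"):
            self.log_beta_on = np.log(model._vec("beta_on"))
            self.log_beta_off = np.log(model._vec("beta_off"))
        self.theta = model.interactions.theta_matrix()
        self.h = model.interactions.h_matrix()
        self.gamma = model.interactions.gamma
        self.protein_max = model.protein_max
        return self

    def rates(self, x: np.ndarray, q: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """k_on, k_off for a batch.

        ``x``: (n, 3) fractional protein abundances; ``q``: (2,) stimulus
        intensities.  Returns two (n, 3) arrays.
        """
        log_phi_on = _log_phi_matrix(x, q, self.theta, self.h, self.gamma)
        log_phi_off = _log_phi_matrix(x, q, -self.theta, self.h, self.gamma)
        kon = self.kon_min + self.kon_max * expit(self.log_beta_on + log_phi_on)
        koff = self.koff_min + self.koff_max * expit(self.log_beta_off + log_phi_off)
        return kon, koff
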