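"""Reaction-network definitions for collective-foraging feedback models.

A colony of foragers allocates itself over ``n`` forage patches of quality
``q_i``.  Each individual is either uncommitted (species ``U``) or committed
to patch ``i``.  Three model variants are expressed as mass-action reaction
networks over the species ``{U, 1..n}``:

* ``positive_only`` — quality-sensitive independent discovery, constant
  abandonment (leak), and quality-insensitive recruitment ``r_i = rho``.
* ``negative_feedback`` — quality-sensitive recruitment ``r_i = rho*q_i``
  plus quality-insensitive stop signalling (self-inhibition) at rate ``z``.
* ``asocial`` — discovery and abandonment only (no social feedback).

The compiled :class:`ReactionSystem` is the single representation shared by
the deterministic mean-field engine and the exact stochastic engine.

Species ordering convention: index 0 is the uncommitted pool ``U``; indices
``1..n`` are the patches in input order.  All state vectors in the package
follow this order.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ModelVariant",
    "PatchEnvironment",
    "TargetDistribution",
    "RateParameters",
    "Reaction",
    "ReactionSystem",
    "make_environment",
    "target_distribution",
    "make_rates",
    "build_model",
    "assemble_system",
    "system_from_config",
    "system_to_config",
]


class ModelVariant(str, enum.Enum):
    """The three analysed model variants."""

    POSITIVE_ONLY = "positive_only"
    NEGATIVE_FEEDBACK = "negative_feedback"
    ASOCIAL = "asocial"


def _as_variant(variant: "ModelVariant | str") -> ModelVariant:
    return ModelVariant(variant)


@dataclass(frozen=True)
class PatchEnvironment:
    """The ``n`` forage patches and their (dimensionless) qualities ``q_i``.

    Qualities must be positive and finite; they need not be normalised,
    since only quality ratios enter the target distribution.
    """

    qualities: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.qualities, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("qualities must be a non-empty 1-D vector")
        if not np.all(np.isfinite(q)) or np.any(q <= 0.0):
            raise ValueError("all patch qualities must be finite and > 0")
        q = q.copy()
        q.flags.writeable = False
        object.__setattr__(self, "qualities", q)

    @property
    def n(self) -> int:
        """Number of forage patches."""
        return int(self.qualities.size)


def make_environment(qualities: Sequence[float]) -> PatchEnvironment:
    """Validate patch qualities and build a :class:`PatchEnvironment`."""
    return PatchEnvironment(np.asarray(qualities, dtype=float))


@dataclass(frozen=True)
class TargetDistribution:
    """Desired allocation of committed foragers, one fraction per patch.

    Entries are positive and sum to one: the target allocates the whole
    colony across patches; the small uncommitted residual at equilibrium is
    a model outcome, not part of the target.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0.0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("target values must be positive and sum to 1")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


def target_distribution(env: PatchEnvironment) -> TargetDistribution:
    """Quality-proportional target: ``x_i* = q_i / sum_j q_j``."""
    q = env.qualities
    return TargetDistribution(q / q.sum())


@dataclass(frozen=True)
class RateParameters:
    """Individual transition rates (units: events per model time unit).

    ``per_patch_recruitment`` is derived from the variant and the
    recruitment coefficient ``rho``: ``rho`` for positive-only,
    ``rho*q_i`` for negative-feedback, 0 for asocial.  It is stored (not
    recomputed) so that custom rate-function candidates from the
    parameterisation search can reuse the same container.
    """

    abandonment: float
    average_recruitment: float
    recruitment_coefficient: float
    stop_signal: float
    per_patch_recruitment: np.ndarray

    def __post_init__(self) -> None:
        for name in ("abandonment", "average_recruitment",
                     "recruitment_coefficient", "stop_signal"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0")
            object.__setattr__(self, name, v)
        r = np.asarray(self.per_patch_recruitment, dtype=float)
        if np.any(r < 0.0) or not np.all(np.isfinite(r)):
            raise ValueError("per-patch recruitment rates must be finite and >= 0")
        r = r.copy()
        r.flags.writeable = False
        object.__setattr__(self, "per_patch_recruitment", r)


def make_rates(
    variant: "ModelVariant | str",
    env: PatchEnvironment,
    *,
    a: float,
    r: float,
    rho: float,
    z: float = 0.0,
) -> RateParameters:
    """Derive the full rate set for a variant from ``(a, r, rho, z)``.

    The per-patch recruitment vector is a pure function of the variant:
    never set it independently.  A log warning is emitted when recruitment
    is not much faster than independent discovery (``r_i >> q_i`` is the
    biological regime, not a mathematical requirement).
    """
    variant = _as_variant(variant)
    if variant is not ModelVariant.NEGATIVE_FEEDBACK and z != 0.0:
        raise ValueError(f"stop-signal rate z must be 0 for variant {variant.value!r}")
    if variant is ModelVariant.POSITIVE_ONLY:
        r_i = np.full(env.n, float(rho))
    elif variant is ModelVariant.NEGATIVE_FEEDBACK:
        r_i = float(rho) * env.qualities
    else:
        r_i = np.zeros(env.n)
    if variant is not ModelVariant.ASOCIAL and np.any(r_i < 10.0 * env.qualities):
        log.warning(
            "recruitment rates are not >> discovery rates "
            "(min r_i/q_i = %.3g); outside the biological regime",
            float(np.min(r_i / env.qualities)),
        )
    return RateParameters(
        abandonment=a,
        average_recruitment=r,
        recruitment_coefficient=rho,
        stop_signal=z,
        per_patch_recruitment=r_i,
    )


UNARY = "unary"
BIMOLECULAR = "bimolecular"


@dataclass(frozen=True)
class Reaction:
    """One state-change reaction with a mass-action rate law.

    ``reactants`` and ``products`` are species index multisets (tuples,
    possibly with repeats); species 0 is U.  Every reaction conserves the
    individual count, so the tuples always have equal length.
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate_constant: float
    kind: str
    label: str

    def net_change(self, n_species: int) -> np.ndarray:
        """Net change of species counts when this reaction fires once."""
        net = np.zeros(n_species, dtype=np.int64)
        for s in self.reactants:
            net[s] -= 1
        for s in self.products:
            net[s] += 1
        return net

    @property
    def conserves_count(self) -> bool:
        return len(self.reactants) == len(self.products)


@dataclass
class ReactionSystem:
    """A model variant compiled to a reaction list shared by both engines."""

    environment: PatchEnvironment
    rates: RateParameters
    variant: ModelVariant
    reactions: tuple[Reaction, ...]
    _compiled: "tuple | None" = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.environment.n

    @property
    def n_species(self) -> int:
        return self.environment.n + 1

    def compiled(self) -> "tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]":
        """Arrays ``(kind, sA, sB, rate, net)`` consumed by the engines.

        kind 0: unary in sA; kind 1: bimolecular distinct (sA, sB);
        kind 2: bimolecular same-species (sA twice).
        """
        if self._compiled is None:
            m = len(self.reactions)
            kind = np.zeros(m, dtype=np.int64)
            s_a = np.zeros(m, dtype=np.int64)
            s_b = np.zeros(m, dtype=np.int64)
            rate = np.zeros(m, dtype=np.float64)
            net = np.zeros((m, self.n_species), dtype=np.int64)
            for j, rx in enumerate(self.reactions):
                rate[j] = rx.rate_constant
                net[j] = rx.net_change(self.n_species)
                if rx.kind == UNARY:
                    kind[j] = 0
                    (s_a[j],) = rx.reactants
                else:
                    a_, b_ = rx.reactants
                    if a_ == b_:
                        kind[j] = 2
                        s_a[j] = s_b[j] = a_
                    else:
                        kind[j] = 1
                        s_a[j], s_b[j] = a_, b_
            net.flags.writeable = False
            self._compiled = (kind, s_a, s_b, rate, net)
        return self._compiled

    def describe(self) -> str:
        """Human-readable reaction listing for logs."""
        names = ["U"] + [f"X{i}" for i in range(1, self.n + 1)]

        def side(ms: tuple[int, ...]) -> str:
            return " + ".join(names[s] for s in ms)

        lines = [f"{self.variant.value}: {len(self.reactions)} reactions, "
                 f"n={self.n} patches, q={np.array2string(self.environment.qualities)}"]
        for rx in self.reactions:
            lines.append(
                f"  {rx.label:<14s} {side(rx.reactants)} -> {side(rx.products)}"
                f"   k = {rx.rate_constant:g} ({rx.kind})"
            )
        return "\n".join(lines)


def assemble_system(
    env: PatchEnvironment,
    a: float,
    per_patch_recruitment: np.ndarray,
    z: float,
    variant: "ModelVariant | str" = ModelVariant.NEGATIVE_FEEDBACK,
    *,
    average_recruitment: "float | None" = None,
    recruitment_coefficient: "float | None" = None,
    include_recruitment: "bool | None" = None,
    include_stop: "bool | None" = None,
) -> ReactionSystem:
    """Low-level constructor: compile an arbitrary rate assignment.

    This is the extension point used by the rate-function search, which
    explores recruitment/stop-signal combinations outside the three named
    variants (e.g. constant recruitment together with stop signalling).
    :func:`build_model` is the validated public entry for the named
    variants.
    """
    variant = _as_variant(variant)
    r_i = np.asarray(per_patch_recruitment, dtype=float)
    if r_i.shape != (env.n,):
        raise ValueError("per-patch recruitment must have one rate per patch")
    if include_recruitment is None:
        include_recruitment = variant is not ModelVariant.ASOCIAL
    if include_stop is None:
        include_stop = variant is ModelVariant.NEGATIVE_FEEDBACK
    rates = RateParameters(
        abandonment=a,
        average_recruitment=(float(np.mean(r_i)) if average_recruitment is None
                             else float(average_recruitment)),
        recruitment_coefficient=(float(np.max(r_i, initial=0.0))
                                 if recruitment_coefficient is None
                                 else float(recruitment_coefficient)),
        stop_signal=z,
        per_patch_recruitment=r_i,
    )
    reactions: list[Reaction] = []
    q = env.qualities
    for i in range(1, env.n + 1):
        reactions.append(Reaction((0,), (i,), float(q[i - 1]), UNARY, f"discover_{i}"))
    for i in range(1, env.n + 1):
        reactions.append(Reaction((i,), (0,), float(a), UNARY, f"abandon_{i}"))
    if include_recruitment:
        for i in range(1, env.n + 1):
            reactions.append(
                Reaction((0, i), (i, i), float(r_i[i - 1]), BIMOLECULAR, f"recruit_{i}")
            )
    if include_stop:
        for i in range(1, env.n + 1):
            reactions.append(
                Reaction((i, i), (0, i), float(z), BIMOLECULAR, f"stop_{i}")
            )
    return ReactionSystem(env, rates, variant, tuple(reactions))


def build_model(
    variant: "ModelVariant | str",
    env: PatchEnvironment,
    rates: RateParameters,
) -> ReactionSystem:
    """Compile a named variant into its reaction system.

    Per patch ``i``: discovery ``U -> i`` at ``q_i``; abandonment
    ``i -> U`` at ``a``; for social variants recruitment ``U + i -> 2i`` at
    ``r_i``; for the negative-feedback variant stop signalling (same-patch
    self-inhibition) ``i + i -> U + i`` at ``z``.  Cross-patch inhibition
    is never generated.
    """
    variant = _as_variant(variant)
    if variant is not ModelVariant.NEGATIVE_FEEDBACK and rates.stop_signal > 0.0:
        raise ValueError(
            f"variant {variant.value!r} must have z = 0 (got z = {rates.stop_signal})"
        )
    expected = {
        ModelVariant.POSITIVE_ONLY:
            np.full(env.n, rates.recruitment_coefficient),
        ModelVariant.NEGATIVE_FEEDBACK:
            rates.recruitment_coefficient * env.qualities,
        ModelVariant.ASOCIAL: np.zeros(env.n),
    }[variant]
    if not np.allclose(rates.per_patch_recruitment, expected, rtol=1e-12, atol=1e-12):
        raise ValueError(
            f"per-patch recruitment inconsistent with variant {variant.value!r}"
        )
    return assemble_system(
        env,
        rates.abandonment,
        rates.per_patch_recruitment,
        rates.stop_signal,
        variant,
        average_recruitment=rates.average_recruitment,
        recruitment_coefficient=rates.recruitment_coefficient,
    )


def system_to_config(system: ReactionSystem) -> dict:
    """Serialise a named-variant system to a plain config mapping."""
    return {
        "variant": system.variant.value,
        "qualities": [float(v) for v in system.environment.qualities],
        "a": system.rates.abandonment,
        "r": system.rates.average_recruitment,
        "z": system.rates.stop_signal,
        "rho": system.rates.recruitment_coefficient,
    }


def system_from_config(config: dict) -> ReactionSystem:
    """Build a named-variant system from a config mapping.

    Declared keys: ``variant``, ``qualities``, ``a``, ``r``, ``z``,
    optional explicit ``rho`` (otherwise derived by recruitment
    equalisation between variants).
    """
    from . import parameterisation  # deferred: parameterisation imports us

    variant = _as_variant(config["variant"])
    env = make_environment(config["qualities"])
    a = float(config["a"])
    r = float(config.get("r", 0.0))
    z = float(config.get("z", 0.0))
    rho = config.get("rho")
    if rho is None:
        rho = parameterisation.equalise_recruitment(r, env, variant) if r > 0 else 0.0
    rates = make_rates(variant, env, a=a, r=r, rho=float(rho), z=z)
    return build_model(variant, env, rates)
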