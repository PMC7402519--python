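"""Heart-failure remodelling of the atrial cell parameters.

Short-term HF in the canine atrium (ventricular-tachypacing model) changes seven
cellular parameters; each is represented as a pure multiplicative transform with
an independent enable flag so single-knockout and graded variants compose
naturally.  The default factors encode the HF phenotype with prolonged APD:
reduced I_Ca, I_to and I_Ks densities, reduced SERCA2a, RyR2 and calsequestrin
protein, and increased SERCA affinity for Ca2+ (lower K_up) standing in for
increased phospholamban phosphorylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from canatrial.cell_model import CellParameters

__all__ = ["RemodellingConfig", "hf_default_config", "apply_remodelling",
           "REMODELLED_PARAMS"]

# parameter-set attribute touched by each remodelling entry
REMODELLED_PARAMS = {
    "g_ca": "g_ca",
    "g_to": "g_to",
    "g_ks": "g_ks",
    "j_up_max": "j_up_max",
    "k_up": "k_up",
    "j_rel_max": "j_rel_max",
    "csqn_max": "csqn_max",
}


@dataclass(frozen=True)
class RemodellingConfig:
    """Seven dimensionless scale factors with per-parameter enable flags."""

    g_ca_scale: float = 1.0
    g_to_scale: float = 1.0
    g_ks_scale: float = 1.0
    j_up_max_scale: float = 1.0
    k_up_scale: float = 1.0
    j_rel_max_scale: float = 1.0
    csqn_max_scale: float = 1.0
    enabled: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in REMODELLED_PARAMS:
            scale = getattr(self, f"{name}_scale")
            if not scale > 0:
                raise ValueError(f"{name}_scale must be strictly positive")
        unknown = set(self.enabled) - set(REMODELLED_PARAMS)
        if unknown:
            raise ValueError(f"unknown remodelling entries: {sorted(unknown)}")
        object.__setattr__(self, "enabled", frozenset(self.enabled))

    def factor(self, name: str) -> float:
        """Effective multiplier for a parameter (1.0 when disabled)."""
        return getattr(self, f"{name}_scale") if name in self.enabled else 1.0

    def disable(self, name: str) -> "RemodellingConfig":
        """Copy with one entry switched off (the single-knockout variant)."""
        if name not in REMODELLED_PARAMS:
            raise ValueError(f"unknown remodelling entry: {name}")
        return replace(self, enabled=self.enabled - {name})

    def with_scale(self, name: str, scale: float) -> "RemodellingConfig":
        """Copy with one entry enabled at an arbitrary factor."""
        if name not in REMODELLED_PARAMS:
            raise ValueError(f"unknown remodelling entry: {name}")
        return replace(self, enabled=self.enabled | {name},
                       **{f"{name}_scale": scale})

    def reciprocal(self) -> "RemodellingConfig":
        """Elementwise reciprocal with the same enable flags."""
        kw = {f"{n}_scale": 1.0 / getattr(self, f"{n}_scale")
              for n in REMODELLED_PARAMS}
        return RemodellingConfig(enabled=self.enabled, **kw)

    def to_dict(self) -> dict:
        d = {f"{n}_scale": getattr(self, f"{n}_scale") for n in REMODELLED_PARAMS}
        d["enabled"] = sorted(self.enabled)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RemodellingConfig":
        d = dict(d)
        enabled = frozenset(d.pop("enabled", ()))
        return cls(enabled=enabled, **d)


def hf_default_config() -> RemodellingConfig:
    """The full HF remodelling phenotype, all seven entries enabled.

    Factors: G_Ca -30%, G_to -50%, G_Ks -45%, J_up(max) -30%, K_up -78%,
    J_rel(max) -60%, [Csqn]_max -15%.
    """
    return RemodellingConfig(
        g_ca_scale=0.70,
        g_to_scale=0.50,
        g_ks_scale=0.55,
        j_up_max_scale=0.70,
        k_up_scale=0.22,
        j_rel_max_scale=0.40,
        csqn_max_scale=0.85,
        enabled=frozenset(REMODELLED_PARAMS),
    )


def apply_remodelling(base: CellParameters,
                      cfg: RemodellingConfig) -> CellParameters:
    """New parameter set with each enabled entry multiplied by its factor.

    Pure transform: ``base`` is never mutated, all untouched fields are
    copied bit-identically.
    """
    kw = {}
    for name, attr in REMODELLED_PARAMS.items():
        f = cfg.factor(name)
        if f != 1.0:
            kw[attr] = getattr(base, attr) * f
    return base.replace(**kw) if kw else base.replace()
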