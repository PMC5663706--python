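"""Virtual PKS assembly line: backbone predictions from module
architecture.

Chain extension is decarboxylative condensation of an (alkyl)malonyl
extender: every extension module adds two backbone carbons. The AT
domain picks the extender and hence the alpha substituent (malonyl ->
H, methylmalonyl -> CH3); the ACTIVE reductive domains set the
beta-carbon state (none -> ketone, KR -> hydroxyl, KR+DH -> enoyl,
KR+DH+ER -> methylene). Domains present in sequence but catalytically
inactive contribute nothing. Starter-unit carbons are a parameter;
post-PKS tailoring, cyclisation regiochemistry and stereochemistry are
deliberately outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .model import HybridRecord, ModuleDef, PKSCluster

__all__ = [
    "ProductPrediction",
    "predict_product",
    "carbon_delta",
    "architecture_table",
    "extension_modules_of",
]

ALPHA_OF_SUBSTRATE = {"malonyl": "H", "methylmalonyl": "CH3", "none": "H"}


def extension_modules_of(arch) -> list[ModuleDef]:
    """Extension modules of a cluster, hybrid record or module list."""
    if isinstance(arch, PKSCluster):
        return arch.extension_modules
    if isinstance(arch, HybridRecord):
        if arch.modules is None:
            raise ValidationError("hybrid record carries no module architecture")
        return [m for m in arch.modules if m.is_extension]
    return [m for m in arch if m.is_extension]


def _beta_state(module: ModuleDef) -> str:
    active = module.active_kinds()
    if "KR" not in active:
        return "ketone"
    if "DH" not in active:
        return "hydroxyl"
    if "ER" not in active:
        return "enoyl"
    return "methylene"


@dataclass
class ProductPrediction:
    """Predicted polyketide backbone: carbon count and per-extension
    alpha substituent and beta-carbon oxidation state."""

    n_extension_modules: int
    starter_carbons: int
    backbone_carbons: int
    alpha_substituents: list[str]
    beta_states: list[str]
    viable: bool
    reasons: list[str] = field(default_factory=list)
    ring_atoms_delta_vs_parent: int | None = None

    def __post_init__(self):
        if self.backbone_carbons != self.starter_carbons + 2 * self.n_extension_modules:
            raise ValidationError("backbone carbon bookkeeping violated")


def predict_product(arch, starter_carbons: int = 7,
                    parent: PKSCluster | None = None) -> ProductPrediction:
    """Walk the assembly line left to right and predict the product
    backbone. Modules missing a mandatory KS/AT/ACP make the
    prediction non-viable (with a reason) rather than raising."""
    modules = extension_modules_of(arch)
    if not modules:
        raise ValidationError("architecture has no extension modules")
    reasons: list[str] = []
    alphas: list[str] = []
    betas: list[str] = []
    for m in modules:
        kinds = {d.kind for d in m.domains}
        missing = {"KS", "AT", "ACP"} - kinds
        if missing:
            reasons.append(f"module {m.index} missing {'/'.join(sorted(missing))}")
        alphas.append(ALPHA_OF_SUBSTRATE[m.at_substrate])
        betas.append(_beta_state(m))
    n = len(modules)
    pred = ProductPrediction(
        n_extension_modules=n,
        starter_carbons=starter_carbons,
        backbone_carbons=starter_carbons + 2 * n,
        alpha_substituents=alphas,
        beta_states=betas,
        viable=not reasons,
        reasons=reasons,
    )
    if parent is not None:
        pred.ring_atoms_delta_vs_parent = carbon_delta(parent, arch)
    return pred


def carbon_delta(parent_arch, hybrid_arch) -> int:
    """Signed backbone-carbon change between two architectures:
    2 x (extension modules in hybrid - extension modules in parent)."""
    return 2 * (
        len(extension_modules_of(hybrid_arch)) - len(extension_modules_of(parent_arch))
    )


def architecture_table(arch) -> pd.DataFrame:
    """One row per module: position, origin (native index, or "i/j" for
    chimeric modules of a hybrid), domain complement (inactive domains
    in lowercase), AT substrate and active flags."""
    if isinstance(arch, HybridRecord):
        modules = arch.modules or []
        origins = arch.origins or [str(m.index) for m in modules]
    elif isinstance(arch, PKSCluster):
        modules = arch.modules
        origins = [str(m.index) for m in modules]
    else:
        modules = list(arch)
        origins = [str(m.index) for m in modules]
    rows = []
    for m, origin in zip(modules, origins):
        complement = "-".join(
            d.kind if d.active else d.kind.lower() for d in m.domains
        )
        rows.append(
            {
                "position": m.index,
                "origin": origin,
                "domains": complement,
                "at_substrate": m.at_substrate,
                "active": ",".join(sorted(m.active_kinds())),
            }
        )
    return pd.DataFrame(rows, columns=["position", "origin", "domains", "at_substrate", "active"])
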