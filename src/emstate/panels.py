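"""Gene panels marking mesenchymal, epithelial and stem transcriptional states.

Default panels carry the mesenchymal and epithelial marker genes named in the
main text of the underlying study design: canonical EMT transcription factors
and structural markers for MES, and E-cadherin plus keratins 8/18 for EPITH.
Organ-specific STEM panels are dataset-dependent and must be supplied via a
config file (or taken from the synthetic scenario's own panels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .data_model_io import (
    ExpressionMatrix,
    ValidationError,
    canonical_gene_id,
    logger,
)

CATEGORIES = ("MES", "EPITH", "STEM")

#: mesenchymal drivers/markers: SNAIL family, N-/P-cadherin, ZEB and TWIST
#: factors, fibronectin, vimentin
DEFAULT_MES_GENES = (
    "SNAI1", "SNAI2", "SNAI3", "CDH2", "CDH3", "ZEB1", "ZEB2",
    "FN1", "VIM", "TWIST1", "TWIST2",
)
#: epithelial markers: E-cadherin and cytokeratins 8/18
DEFAULT_EPITH_GENES = ("CDH1", "KRT8", "KRT18")


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered gene list with a state category.

    STEM panels are keyed by (tissue_class, organ) so each cell is scored by
    the stem panel of its own tissue/organ; MES and EPITH panels are global
    and carry no key.
    """

    name: str
    category: str
    genes: tuple[str, ...]
    key: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"panel {self.name!r}: category must be one of {CATEGORIES}"
            )
        if not self.genes:
            raise ValidationError(f"panel {self.name!r}: empty gene list")
        canon = [canonical_gene_id(g) for g in self.genes]
        if len(set(canon)) != len(canon):
            dupes = sorted({g for g in canon if canon.count(g) > 1})
            raise ValidationError(
                f"panel {self.name!r}: duplicated genes {dupes}"
            )
        if self.category == "STEM" and self.key is None:
            raise ValidationError(
                f"STEM panel {self.name!r} requires a (tissue_class, organ) key"
            )
        if self.category != "STEM" and self.key is not None:
            raise ValidationError(
                f"{self.category} panel {self.name!r} must not carry a key"
            )


def default_panels() -> list[GenePanel]:
    """The text-named MES and EPITH marker panels; no STEM defaults."""
    return [
        GenePanel("MES_default", "MES", DEFAULT_MES_GENES),
        GenePanel("EPITH_default", "EPITH", DEFAULT_EPITH_GENES),
    ]


def load_panels(config_path: str | Path) -> list[GenePanel]:
    """Load panels from a YAML/JSON config.

    Schema: ``{panels: [{name, category, genes: [...], tissue_class?,
    organ?}]}``.  A config that defines MES and/or EPITH panels replaces the
    defaults entirely (no merge).
    """
    path = Path(config_path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict) or "panels" not in data:
        raise ValidationError(f"{path}: config must hold a 'panels' list")
    panels: list[GenePanel] = []
    for entry in data["panels"]:
        missing = {"name", "category", "genes"} - set(entry)
        if missing:
            raise ValidationError(
                f"{path}: panel entry missing fields {sorted(missing)}"
            )
        key = None
        if entry.get("tissue_class") is not None or entry.get("organ") is not None:
            key = (str(entry.get("tissue_class")), str(entry.get("organ")))
        panels.append(GenePanel(
            name=str(entry["name"]),
            category=str(entry["category"]),
            genes=tuple(str(g) for g in entry["genes"]),
            key=key,
        ))
    return panels


def resolve_panel(panel: GenePanel, matrix: ExpressionMatrix
                  ) -> tuple[list[str], list[str]]:
    """Partition panel genes by presence in the matrix, order preserved.

    Matching is canonical (case-insensitive, version suffixes stripped).  A
    panel with no genes present is a hard error: a score over zero genes is
    undefined.  Missing genes are reported with a warning; scores downstream
    are means over the present genes only.
    """
    index = matrix.gene_index()
    present = [g for g in panel.genes if canonical_gene_id(g) in index]
    missing = [g for g in panel.genes if canonical_gene_id(g) not in index]
    if not present:
        raise ValidationError(
            f"panel {panel.name!r}: none of its {len(panel.genes)} genes "
            "are present in the matrix"
        )
    if missing:
        logger.warning("panel %s: %d/%d genes missing from matrix: %s",
                       panel.name, len(missing), len(panel.genes), missing)
    return present, missing


def panels_by_category(panels: list[GenePanel]) -> dict[str, list[GenePanel]]:
    out: dict[str, list[GenePanel]] = {c: [] for c in CATEGORIES}
    for p in panels:
        out[p.category].append(p)
    return out
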