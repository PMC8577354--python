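"""Curated gene signatures and gene-symbol normalization.

Two built-in sets drive the whole pipeline:

* ``ECM_STROMAL`` — 12 genes marking CAF/pericyte-like mesenchymal
  cells of the tumour microenvironment (hallmark CAF/pericyte genes
  plus genes specific to lung perivascular-like cells).
* ``IA`` — an immune-activation set representing a CD8+ T effector
  phenotype: cytolytic effectors, activation markers, the CXCR3
  infiltration axis and the homeostatic regulator IL7R. This set is
  occasionally summarised as "13-gene" in the literature it was curated
  from, but only 12 distinct symbols are enumerated; the registry ships
  those 12 and does not guess a 13th.

Symbol matching is case-insensitive with a small alias map covering the
protein-name spellings common in cytokine panels and flow-cytometry
work (e.g. TGFβ1 → TGFB1, PD-L1 → CD274, CD90 → THY1).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

from .errors import ParseError, ValidationError

# Greek letters as they appear in protein-style names.
_GREEK = str.maketrans({"Α": "A", "Β": "B", "Γ": "G", "Δ": "D"})

#: alias (normalized spelling) -> canonical HGNC-style symbol
ALIASES: dict[str, str] = {
    "TGFB1": "TGFB1",
    "TGF-B1": "TGFB1",
    "TGFB": "TGFB1",
    "IFN-G": "IFNG",
    "IFNG": "IFNG",
    "IL-2": "IL2",
    "IL-4": "IL4",
    "IL-5": "IL5",
    "IL-6": "IL6",
    "IL-7": "IL7",
    "IL-8": "CXCL8",
    "IL8": "CXCL8",
    "IL-10": "IL10",
    "IL-12": "IL12A",
    "IL-13": "IL13",
    "IL-15": "IL15",
    "IL-16": "IL16",
    "IL-17A": "IL17A",
    "IL-1B": "IL1B",
    "IL-7R": "IL7R",
    "CD127": "IL7R",
    "CD90": "THY1",
    "CD73": "NT5E",
    "PD-L1": "CD274",
    "PD-1": "PDCD1",
    "CTLA-4": "CTLA4",
    "GMZA": "GZMA",  # common transposition of GZMA
    "M-CSF": "CSF1",
    "MCSF": "CSF1",
    "GM-CSF": "CSF2",
    "GMCSF": "CSF2",
    "TNF-A": "TNF",
    "TNFA": "TNF",
    "FRACTALKINE": "CX3CL1",
}

_CYTOKINE_PREFIX = re.compile(r"^(IL|CCL|CXCL|CX3CL|XCL)-(\d+[A-Z]?)$")


def normalize_symbol(symbol: str) -> str:
    """Map a gene/protein name to its canonical uppercase symbol.

    Unknown symbols are returned uppercased but otherwise untouched, so
    legitimate hyphenated symbols (e.g. HLA-A) are never mangled.
    """
    if not isinstance(symbol, str) or not symbol.strip():
        raise ValidationError(f"gene symbol must be a non-empty string, got {symbol!r}")
    u = symbol.strip().upper().translate(_GREEK)
    for candidate in (u, u.replace("-", "")):
        if candidate in ALIASES:
            return ALIASES[candidate]
    m = _CYTOKINE_PREFIX.match(u)
    if m:  # IL-6 style protein spellings of cytokine genes
        return m.group(1) + m.group(2)
    return u


@dataclasses.dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene set."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("signature name must be non-empty")
        if len(self.genes) == 0:
            raise ValidationError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dupes = [g for g in self.genes if g in seen or seen.add(g)]
            raise ValidationError(f"signature {self.name!r} has duplicate genes: {dupes}")

    @classmethod
    def build(cls, name: str, symbols: list[str] | tuple[str, ...]) -> "GeneSignature":
        """Construct a signature, normalizing symbols and dropping case."""
        return cls(name=name, genes=tuple(normalize_symbol(s) for s in symbols))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


ECM_STROMAL = GeneSignature(
    name="ECM_STROMAL",
    genes=(
        "VCAN", "FAP", "COL1A1", "POSTN", "THY1", "FBLN1", "TGFB1",
        "IL6", "CSPG4", "PDPN", "HGF", "SERPINE1",
    ),
)

IA = GeneSignature(
    name="IA",
    genes=(
        "IFNG", "GZMA", "GZMB", "GZMK", "PRF1", "GNLY",
        "IL2", "PDCD1", "CD274", "CTLA4", "CXCR3", "IL7R",
    ),
)


def builtin_signatures() -> list[GeneSignature]:
    """The built-in ECM/stromal and immune-activation signatures."""
    return [ECM_STROMAL, IA]


# ---------------------------------------------------------------------------
# file formats: two-column TSV and GMT


def read_signatures_tsv(path: str | Path) -> list[GeneSignature]:
    """Read signatures from a two-column TSV (signature_name, gene_symbol)."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(f"{path}: line {lineno}: expected 'name<TAB>gene'")
            groups.setdefault(parts[0], []).append(parts[1])
    if not groups:
        raise ParseError(f"{path}: no signatures found")
    return [GeneSignature.build(name, genes) for name, genes in groups.items()]


def write_signatures_tsv(signatures: list[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            for gene in sig.genes:
                fh.write(f"{sig.name}\t{gene}\n")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read signatures from a GMT file (name, description, genes...)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need name, description and >=1 gene"
                )
            out.append(GeneSignature.build(parts[0], [g for g in parts[2:] if g]))
    if not out:
        raise ParseError(f"{path}: no signatures found")
    return out


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "stromasig"] + list(sig.genes)) + "\n")
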