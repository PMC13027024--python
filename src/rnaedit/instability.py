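"""Expression-based genomic-instability scores: MSI, TMB, retroelement signature.

MSI is inferred from two expression composites — a mismatch-repair (MMR)
deficiency score over MLH1/MSH2/MSH6/PMS2 and a weighted hypermutator
signature over ten genes — combined by a user-supplied linear decision
boundary. The signature coefficients and the boundary are mandatory
configuration: no published defaults exist, so none are hard-coded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "MMR_GENES",
    "HYPERMUTATOR_GENES",
    "SIGNATURE_FEATURES",
    "MSIScores",
    "SignatureScore",
    "TMBValue",
    "MissingGeneError",
    "mmr_deficiency_score",
    "hypermutator_score",
    "classify_msi",
    "insertional_signature",
    "tmb",
    "load_coefficients",
    "load_boundary",
]

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
HYPERMUTATOR_GENES = (
    "EPM2AIP1", "TTC30A", "SMAP1", "RNLS", "WNT11",
    "SFXN1", "SREBF1", "TYMS", "EIF5AL1", "WDR76",
)
SIGNATURE_FEATURES = ("L1Hs", "L1PA2", "TERT", "APOBEC3B")

DEFAULT_LOG_BASE = 2.0
DEFAULT_PSEUDOCOUNT = 1.0


class MissingGeneError(KeyError):
    """A required gene/feature is absent from the expression data."""


@dataclass(frozen=True)
class MSIScores:
    sample_id: str
    mmr_score: float
    hypermutator_score: float
    call: str  # "MSI" | "MSS" | "undetermined"


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    value: float


@dataclass(frozen=True)
class TMBValue:
    sample_id: str
    mutations: int
    exome_mb: float

    @property
    def tmb(self) -> float:
        return self.mutations / self.exome_mb


def _log(value: float, base: float) -> float:
    return math.log(value) / math.log(base)


def _require(expr_sample: dict, gene: str) -> float:
    try:
        return float(expr_sample[gene])
    except KeyError:
        raise MissingGeneError(f"required gene absent from expression data: {gene}") from None


def mmr_deficiency_score(
    expr_sample: dict[str, float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float = DEFAULT_LOG_BASE,
) -> float:
    """Negative sum of log expression over the four core MMR genes.

    Higher values mean lower MMR gene expression, i.e. more likely MMR
    deficiency.
    """
    return -sum(
        _log(_require(expr_sample, g) + pseudocount, log_base) for g in MMR_GENES
    )


def hypermutator_score(
    expr_sample: dict[str, float],
    coefficients: dict[str, float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float = DEFAULT_LOG_BASE,
) -> float:
    """Weighted sum of log expression over the hypermutator signature genes."""
    missing = [g for g in coefficients if g not in expr_sample]
    if missing:
        raise MissingGeneError(
            f"signature gene(s) absent from expression data: {', '.join(missing)}"
        )
    return sum(
        w * _log(float(expr_sample[g]) + pseudocount, log_base)
        for g, w in coefficients.items()
    )


def classify_msi(
    mmr_score: float,
    hyper_score: float,
    boundary: dict[str, float],
) -> str:
    """Linear decision: MSI iff a*mmr + b*hyper + c > 0 (ties -> MSS)."""
    missing = {"a", "b", "c"} - set(boundary)
    if missing:
        raise ValueError(f"boundary config missing key(s): {', '.join(sorted(missing))}")
    value = boundary["a"] * mmr_score + boundary["b"] * hyper_score + boundary["c"]
    return "MSI" if value > 0 else "MSS"


def insertional_signature(
    expr_sample: dict[str, float],
    sample_id: str = "",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float = DEFAULT_LOG_BASE,
) -> SignatureScore:
    """Retroelement-activity proxy: summed log expression of the four features."""
    value = sum(
        _log(_require(expr_sample, f) + pseudocount, log_base) for f in SIGNATURE_FEATURES
    )
    return SignatureScore(sample_id=sample_id, value=value)


def tmb(n_coding_variants: int, exome_mb: float, sample_id: str = "") -> TMBValue:
    """Somatic coding mutations per megabase of coding exome."""
    if exome_mb <= 0:
        raise ValueError(f"exome size must be positive, got {exome_mb}")
    if n_coding_variants < 0:
        raise ValueError("variant count must be non-negative")
    return TMBValue(sample_id=sample_id, mutations=n_coding_variants, exome_mb=exome_mb)


def load_coefficients(path: str | Path) -> dict[str, float]:
    """Read a gene/weight TSV for the hypermutator signature."""
    coeffs: dict[str, float] = {}
    with Path(path).open() as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["gene", "weight"]:
                    raise ValueError(f"{path}: expected columns gene, weight")
                continue
            coeffs[fields[0]] = float(fields[1])
    if not coeffs:
        raise ValueError(f"{path}: no coefficients")
    return coeffs


def load_boundary(path: str | Path) -> dict[str, float]:
    """Read the MSI decision-line parameters (YAML or JSON with keys a, b, c)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict) or {"a", "b", "c"} - set(data):
        raise ValueError(f"{path}: boundary config must provide keys a, b, c")
    return {k: float(data[k]) for k in ("a", "b", "c")}
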