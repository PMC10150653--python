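"""Core domain containers.

The analysis pipeline passes four kinds of object between stages:

* :class:`ExpressionMatrix` — observations (cells or bulk samples) x genes,
  non-negative values on a declared scale.  The scale is *declared, never
  inferred*: the cell-level EMT-class thresholds (0 / 5, log-normalised
  units) and the bulk thresholds (2,000 / 5,000, linear units) are
  incompatible, and silently applying one to the other would corrupt every
  downstream classification.
* :class:`GeneSignature` / :class:`SignatureRegistry` — named gene sets
  with an aggregation rule (``sum_difference`` for the EMT score, ``mean``
  for invasion / stemness / angiogenesis scores).
* :class:`ScoreTable` — per-observation signature scores plus per-signature
  metadata (genes used, genes missing).
* :class:`MethylationTable` — sample x probe M-values (log2 methylated /
  unmethylated intensity ratios, unbounded reals) with tumour/normal group
  labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DuplicateIDError, ValidationError

SCALES = ("log_normalized", "linear")
OBS_KINDS = ("cell", "bulk_sample")
CELL_TYPES = (
    "malignant",
    "normal_epithelial",
    "endothelial",
    "perivascular",
    "CAF",
    "immune",
    "other",
)

# Twelve-gene EMT signature: epithelial markers are subtracted from
# mesenchymal markers, so higher sEMT = more mesenchymal.
EMT_EPITHELIAL_GENES = ("CDH1", "GRHL2", "ITGB4", "KRT5", "KRT8", "FST")
EMT_MESENCHYMAL_GENES = ("CDH2", "ZEB1", "VIM", "MMP1", "FN1", "TGFB1I1")


def _check_unique(ids, kind: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise DuplicateIDError(kind, dups)


@dataclass
class ExpressionMatrix:
    """Dense observations x genes matrix with declared scale and kind.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in
    observation ``obs_ids[i]``.  Absent measurements in sparse inputs are 0
    (the usual single-cell convention; "expressing" downstream means
    value > detection threshold).
    """

    obs_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scale: str
    obs_kind: str

    def __post_init__(self) -> None:
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise ConfigError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.obs_kind not in OBS_KINDS:
            raise ConfigError(
                f"unknown obs_kind {self.obs_kind!r}; expected one of {OBS_KINDS}"
            )
        if self.values.ndim != 2 or self.values.shape != (
            len(self.obs_ids),
            len(self.gene_ids),
        ):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.obs_ids)} obs x {len(self.gene_ids)} genes"
            )
        _check_unique(self.obs_ids, "observation")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values contain NaN or infinity")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression of one gene across all observations (1-D view)."""
        from .errors import MissingGeneError

        if gene not in self._gene_index:
            raise MissingGeneError([gene])
        return self.values[:, self._gene_index[gene]]

    def subset_obs(self, obs_ids) -> "ExpressionMatrix":
        index = {o: i for i, o in enumerate(self.obs_ids)}
        rows = [index[o] for o in obs_ids]
        return ExpressionMatrix(
            obs_ids=list(obs_ids),
            gene_ids=list(self.gene_ids),
            values=self.values[rows, :],
            scale=self.scale,
            obs_kind=self.obs_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with its aggregation rule.

    ``sum_difference``: score = sum(positive_set) - sum(negative_set)
    (mesenchymal minus epithelial for the EMT score).
    ``mean``: score = mean over the positive_set genes present in the
    matrix; negative_set must be empty.
    """

    name: str
    aggregation: str
    positive_set: tuple[str, ...]
    negative_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.aggregation not in ("sum_difference", "mean"):
            raise ValidationError(
                f"signature {self.name!r}: unknown aggregation {self.aggregation!r}"
            )
        pos, neg = set(self.positive_set), set(self.negative_set)
        if pos & neg:
            raise ValidationError(
                f"signature {self.name!r}: genes in both roles: "
                f"{', '.join(sorted(pos & neg))}"
            )
        if len(pos) != len(self.positive_set) or len(neg) != len(self.negative_set):
            raise ValidationError(f"signature {self.name!r}: duplicate genes in a role")
        if self.aggregation == "sum_difference":
            if not pos or not neg:
                raise ValidationError(
                    f"signature {self.name!r}: sum_difference needs both "
                    "a positive and a negative set"
                )
        else:
            if neg:
                raise ValidationError(
                    f"signature {self.name!r}: mean signatures take no negative set"
                )
            if not pos:
                raise ValidationError(f"signature {self.name!r}: empty signature")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.positive_set) + tuple(self.negative_set)


def default_emt_signature() -> GeneSignature:
    """The built-in 12-gene EMT score: sum(mesenchymal) - sum(epithelial)."""
    return GeneSignature(
        name="sEMT",
        aggregation="sum_difference",
        positive_set=EMT_MESENCHYMAL_GENES,
        negative_set=EMT_EPITHELIAL_GENES,
    )


@dataclass
class SignatureRegistry:
    """Name -> signature map; ships the EMT score built in.

    Invasion (sInv), stemness (sCSC) and angiogenesis (sAng) gene lists are
    study-supplied and loaded from signature files rather than hard-coded.
    """

    signatures: dict[str, GeneSignature] = field(default_factory=dict)

    @classmethod
    def with_defaults(cls) -> "SignatureRegistry":
        reg = cls()
        reg.add(default_emt_signature())
        return reg

    def add(self, signature: GeneSignature, replace: bool = False) -> None:
        if signature.name in self.signatures and not replace:
            raise ValidationError(f"signature {signature.name!r} already registered")
        self.signatures[signature.name] = signature

    def __getitem__(self, name: str) -> GeneSignature:
        return self.signatures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.signatures

    def __len__(self) -> int:
        return len(self.signatures)

    def names(self) -> list[str]:
        return list(self.signatures)

    def overlap_report(self) -> dict[str, list[str]]:
        """Genes appearing in more than one signature -> signature names.

        With the study's default lists the expected report is exactly
        ``{"MMP1": ["sCSC", "sEMT"]}``: MMP1 sits in both the EMT and the
        stemness signature, which are otherwise non-overlapping.
        """
        membership: dict[str, set[str]] = {}
        for sig in self.signatures.values():
            for g in sig.genes:
                membership.setdefault(g, set()).add(sig.name)
        return {
            g: sorted(names) for g, names in sorted(membership.items()) if len(names) > 1
        }


@dataclass
class ScoreTable:
    """Per-observation signature scores.

    ``scores`` is indexed by obs_id with one column per signature; the
    scale/obs_kind tags of the source matrix travel with the table so the
    stratification stage can refuse mismatched thresholds.  ``meta`` maps
    signature name -> {"n_genes_used": int, "missing_genes": [..],
    "aggregation": str}.
    """

    scores: pd.DataFrame
    scale: str
    obs_kind: str
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise DuplicateIDError("observation", self.scores.index[self.scores.index.duplicated()])

    @property
    def obs_ids(self) -> list[str]:
        return list(self.scores.index)

    def column(self, name: str) -> pd.Series:
        return self.scores[name]

    def join(self, other: "ScoreTable") -> "ScoreTable":
        if (self.scale, self.obs_kind) != (other.scale, other.obs_kind):
            raise ConfigError("cannot join score tables with different scale tags")
        return ScoreTable(
            scores=self.scores.join(other.scores, how="inner"),
            scale=self.scale,
            obs_kind=self.obs_kind,
            meta={**self.meta, **other.meta},
        )


@dataclass(frozen=True)
class ThresholdConfig:
    """EMT-class boundaries and the expression detection threshold.

    Classes are half-open: low = (-inf, emt_low_upper), med =
    [emt_low_upper, emt_high_lower), high = [emt_high_lower, inf) — a
    real-valued score leaves no unclassifiable band.  ``obs_kind`` records
    which scale the boundaries were set for; cell defaults (0, 5) apply to
    log-normalised per-cell scores, bulk defaults (2,000, 5,000) to
    linear-scale tumour scores.
    """

    emt_low_upper: float
    emt_high_lower: float
    detection_threshold: float = 0.0
    obs_kind: str = "cell"

    def __post_init__(self) -> None:
        if not self.emt_low_upper < self.emt_high_lower:
            raise ConfigError(
                f"emt_low_upper ({self.emt_low_upper}) must be < "
                f"emt_high_lower ({self.emt_high_lower})"
            )
        if self.obs_kind not in OBS_KINDS:
            raise ConfigError(f"unknown obs_kind {self.obs_kind!r}")

    @classmethod
    def cell_defaults(cls) -> "ThresholdConfig":
        return cls(emt_low_upper=0.0, emt_high_lower=5.0, obs_kind="cell")

    @classmethod
    def bulk_defaults(cls) -> "ThresholdConfig":
        return cls(emt_low_upper=2000.0, emt_high_lower=5000.0, obs_kind="bulk_sample")


@dataclass
class MethylationTable:
    """Sample x probe M-value matrix with tumour/normal group labels.

    M-values are unbounded reals; missing probe measurements are NaN
    (explicitly flagged, never silently 0).  The probe set is shared by all
    samples.
    """

    sample_ids: list[str]
    groups: list[str]
    probe_ids: list[str]
    M: np.ndarray
    expression: Mapping[str, float] | None = None  # optional matched expression

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValidationError(
                f"M shape {self.M.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        if len(self.groups) != len(self.sample_ids):
            raise ValidationError("one group label per sample required")
        bad = set(self.groups) - {"tumour", "normal"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.probe_ids, "probe")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.sample_ids, columns=self.probe_ids)
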