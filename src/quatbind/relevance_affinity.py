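"""Biological-relevance assessment and binding-affinity handling.

Small molecules outside the crystallization-additive exclusion list are
biologically relevant by default; peptides and nucleic acids are always
relevant.  Listed molecules go through a rule hierarchy based on the
binding-site size on the quaternary structure, optionally escalated by a
keyword check against a caller-supplied abstract.  The ligand occurrence
number and binding-residue continuity rules used by earlier single-chain
pipelines are deliberately not applied.

Affinities are normalized to the pKd scale (-log10 of a molar
concentration).  A consensus predictor is an ordinary-least-squares fit
of experimental pKd on three physics-based docking scores.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import Ligand
from .site_annotation import BindingSite

__all__ = [
    "ExclusionList",
    "RelevanceVerdict",
    "AffinityRecord",
    "AffinityModel",
    "assess_relevance",
    "read_affinity_table",
    "read_score_table",
    "fit_consensus",
    "predict_consensus",
    "bootstrap_pcc_compare",
]

DEFAULT_MIN_SITE_RESIDUES = 6

BINDING_KEYWORDS = {"bind", "binds", "binding", "bound", "inhibit", "inhibits",
                    "inhibitor", "inhibition", "substrate", "cofactor",
                    "activate", "activates", "activator", "activation"}


@dataclass
class ExclusionList:
    """Crystallization-additive component IDs to subject to relevance rules."""

    comp_ids: set[str]
    source: str = "<memory>"
    checksum: str = ""

    def __post_init__(self) -> None:
        self.comp_ids = {c.strip().upper() for c in self.comp_ids if c.strip()}
        for c in self.comp_ids:
            if not (1 <= len(c) <= 5):
                raise ValueError(f"bad component ID in exclusion list: {c!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionList":
        path = Path(path)
        text = path.read_text()
        ids = {
            line.strip().upper()
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        }
        checksum = hashlib.sha256(text.encode()).hexdigest()[:12]
        return cls(comp_ids=ids, source=str(path), checksum=checksum)

    def __contains__(self, comp_id: str) -> bool:
        return comp_id.upper() in self.comp_ids


@dataclass
class RelevanceVerdict:
    status: str  # relevant | irrelevant | needs_review
    rule_fired: str  # not_in_list | peptide_or_nucleic | site_size_rule | keyword_rule | listed_default
    evidence: str = ""


def _keyword_match(ligand_names: list[str], abstract: str) -> bool:
    """True when a ligand name co-occurs with binding vocabulary in one sentence."""
    sentences = re.split(r"[.!?]+", abstract.lower())
    names = [n.lower() for n in ligand_names if n]
    for sentence in sentences:
        words = set(re.findall(r"[a-z0-9'\-]+", sentence))
        if any(n in sentence for n in names) and words & BINDING_KEYWORDS:
            return True
    return False


def assess_relevance(
    ligand: Ligand,
    site: BindingSite | None,
    exclusion: ExclusionList,
    abstract_text: str | None = None,
    min_site_residues: int = DEFAULT_MIN_SITE_RESIDUES,
    ligand_synonyms: list[str] | None = None,
) -> RelevanceVerdict:
    """Hierarchical biological-relevance verdict for one ligand.

    Peptide and nucleic ligands are relevant unconditionally.  A small
    molecule absent from the exclusion list is relevant by default.  For
    listed molecules: a binding site smaller than ``min_site_residues``
    residues (counted on the full quaternary structure) marks the ligand
    irrelevant; otherwise the entry needs review, unless an abstract is
    supplied and mentions the ligand near binding vocabulary, which
    promotes it to relevant.
    """
    if ligand.kind in ("peptide", "nucleic"):
        return RelevanceVerdict(
            status="relevant",
            rule_fired="peptide_or_nucleic",
            evidence=f"{ligand.kind} ligands are relevant without assessment",
        )
    comp = ligand.comp_id or ligand.ligand_id
    if comp not in exclusion:
        return RelevanceVerdict(
            status="relevant",
            rule_fired="not_in_list",
            evidence=f"{comp} not in exclusion list ({len(exclusion.comp_ids)} IDs)",
        )
    if site is None:
        raise ValueError(f"listed ligand {comp}: binding site required for assessment")
    n = site.n_residues
    if n < min_site_residues:
        return RelevanceVerdict(
            status="irrelevant",
            rule_fired="site_size_rule",
            evidence=f"{n} binding residues < {min_site_residues}",
        )
    if abstract_text is not None:
        names = [comp] + (ligand_synonyms or [])
        if _keyword_match(names, abstract_text):
            return RelevanceVerdict(
                status="relevant",
                rule_fired="keyword_rule",
                evidence=f"abstract links {comp} to binding vocabulary",
            )
    return RelevanceVerdict(
        status="needs_review",
        rule_fired="listed_default",
        evidence=f"listed additive with {n} binding residues; no abstract evidence",
    )


# ---------------------------------------------------------------------------
# Affinity tables
# ---------------------------------------------------------------------------

_UNIT_FACTOR = {
    "M": 1.0,
    "MM": 1e-3,
    "UM": 1e-6, "µM": 1e-6, "μM": 1e-6,
    "NM": 1e-9,
    "PM": 1e-12,
    "FM": 1e-15,
}
_MEASURES = {"KD", "KI", "IC50"}

AFFINITY_COLUMNS = ["pdb_id", "ligand_id", "chain", "measure", "value", "unit", "source"]
SCORE_COLUMNS = ["pdb_id", "ligand_id", "x_xscore", "x_itscore", "x_vina"]


@dataclass
class AffinityRecord:
    kind: str  # experimental | predicted
    value: float  # pKd scale
    raw: str = ""
    source: str = ""
    components: tuple[float, float, float] | None = None


def to_pkd(measure: str, value: float, unit: str) -> float:
    """Normalize an affinity measurement to the pKd scale (-log10 M)."""
    measure = measure.strip().upper()
    unit_key = unit.strip().upper().replace("µ", "U").replace("μ", "U")
    if measure not in _MEASURES:
        raise ValueError(f"unsupported measure {measure!r}")
    if unit_key not in _UNIT_FACTOR:
        raise ValueError(f"unsupported unit {unit!r}")
    molar = float(value) * _UNIT_FACTOR[unit_key]
    if molar <= 0:
        raise ValueError(f"non-positive concentration {value} {unit}")
    return -math.log10(molar)


def read_affinity_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an experimental-affinity TSV and normalize values to pKd.

    Expects the header ``pdb_id ligand_id chain measure value unit source``.
    Returns (accepted rows with a ``pkd`` column, rejected rows with a
    ``reject_reason`` column); unparseable rows are collected, not fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in AFFINITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: affinity table missing columns {missing}")
    accepted, rejects = [], []
    for _, row in df.iterrows():
        try:
            pkd = to_pkd(row["measure"], float(row["value"]), row["unit"])
        except (ValueError, TypeError) as exc:
            rejects.append({**row.to_dict(), "reject_reason": str(exc)})
            continue
        accepted.append({**row.to_dict(), "pkd": pkd})
    return (
        pd.DataFrame(accepted, columns=AFFINITY_COLUMNS + ["pkd"]),
        pd.DataFrame(rejects, columns=AFFINITY_COLUMNS + ["reject_reason"]),
    )


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a docking-score TSV with columns pdb_id ligand_id x_xscore x_itscore x_vina."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: score table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Consensus affinity model
# ---------------------------------------------------------------------------

SCORE_NAMES = ("x_xscore", "x_itscore", "x_vina")


@dataclass
class AffinityModel:
    intercept: float
    weights: np.ndarray  # over (x_xscore, x_itscore, x_vina)
    n_train: int = 0
    pcc_consensus: float = float("nan")
    pcc_univariate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(3)
        if not (np.isfinite(self.weights).all() and np.isfinite(self.intercept)):
            raise ValueError("model coefficients must be finite")


def _pcc(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def fit_consensus(rows: np.ndarray | list) -> AffinityModel:
    """OLS fit of pKd on the three docking scores.

    ``rows`` is an (n, 4) array-like: (x_xscore, x_itscore, x_vina, pKd)
    with n >= 10 complete rows.  Reports the in-sample Pearson
    correlation of the consensus and of each single-score fit.
    """
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValueError("expected rows of (x_xscore, x_itscore, x_vina, pkd)")
    data = data[np.isfinite(data).all(axis=1)]
    if data.shape[0] < 10:
        raise ValueError(f"need >= 10 complete training rows, got {data.shape[0]}")
    X = np.column_stack([np.ones(len(data)), data[:, :3]])
    y = data[:, 3]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design matrix: scores are collinear; remove a feature"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    pcc_uni = {name: _pcc(data[:, i], y) for i, name in enumerate(SCORE_NAMES)}
    return AffinityModel(
        intercept=float(beta[0]),
        weights=beta[1:],
        n_train=len(data),
        pcc_consensus=_pcc(yhat, y),
        pcc_univariate=pcc_uni,
    )


def predict_consensus(model: AffinityModel, components) -> float:
    """Predicted pKd = intercept + weights · (x_xscore, x_itscore, x_vina)."""
    comp = np.asarray(components, dtype=float).reshape(-1)
    if comp.shape != (3,) or not np.isfinite(comp).all():
        raise ValueError("all three score components are required for prediction")
    return float(model.intercept + model.weights @ comp)


@dataclass
class PccComparison:
    delta_mean: float
    ci_low: float
    ci_high: float
    significant: bool


def bootstrap_pcc_compare(
    consensus_pred: np.ndarray,
    single_pred: np.ndarray,
    observed: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> PccComparison:
    """Bootstrap test of PCC(consensus, y) - PCC(single, y).

    Resamples rows with replacement ``n_boot`` times; the improvement is
    significant when the 95% percentile interval of the PCC difference
    excludes zero.  Deterministic given ``seed``.
    """
    c = np.asarray(consensus_pred, dtype=float)
    s = np.asarray(single_pred, dtype=float)
    y = np.asarray(observed, dtype=float)
    if not (len(c) == len(s) == len(y)):
        raise ValueError("prediction and observation vectors must have equal length")
    n = len(y)
    if n < 30:
        raise ValueError(f"need n >= 30 paired observations, got {n}")
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        deltas[b] = _pcc(c[idx], y[idx]) - _pcc(s[idx], y[idx])
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return PccComparison(
        delta_mean=float(deltas.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
    )
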