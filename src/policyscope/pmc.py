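"""Policy Modeling Consistency (PMC) index.

The PMC model scores a policy text against a fixed variable tree: nine
primary variables X1..X9 (policy nature, timeliness, function, theme,
evaluation, audience, tools, incentives, disciplines), each observed
through binary secondary indicators (51 in the default schema).  Every
secondary is coded 1 if the policy addresses it, else 0; a primary's
score is the mean of its secondaries, and the PMC index is the sum of
the nine primary scores, on a 0–9 scale binned as

    Poor [0, 4)   Acceptable [4, 6)   Excellent [6, 8)   Perfect [8, 9].

Primary scores are rounded half-up to two decimals before summation and
the sum re-rounded, which is the convention that reproduces published
PMC tables computed on 2-dp score grids.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "VariableSchema",
    "PolicyCoding",
    "PMCResult",
    "CohortSummary",
    "DEFAULT_SCHEMA",
    "RATINGS",
    "load_schema",
    "score_primary",
    "pmc_index",
    "classify",
    "pmc_matrix",
    "evaluate_policy",
    "cohort_summary",
    "surface_export",
    "read_coding_csv",
    "write_coding_csv",
    "results_table",
    "round2",
]

RATINGS = ("Poor", "Acceptable", "Excellent", "Perfect")

_DEFAULT_PRIMARIES: list[tuple[str, str, list[str]]] = [
    ("X1", "policy nature",
     ["regulation", "guidance", "description", "prediction", "diagnosis", "recommendation"]),
    ("X2", "policy timeliness",
     ["long-term (more than 5 years)", "medium-term (1-5 years)", "short-term (within 1 year)"]),
    ("X3", "policy function",
     ["coordination and cooperation", "rights protection", "institutional constraints",
      "standardized guidance", "supervision and regulation"]),
    ("X4", "policy theme",
     ["primary healthcare", "health promotion", "health equity",
      "healthcare reform and regulation", "chronic disease prevention and control",
      "public health governance"]),
    ("X5", "policy evaluation",
     ["clear objectives", "scientific plan", "detailed content", "sufficient basis"]),
    ("X6", "policy audience",
     ["government", "community", "schools", "enterprises", "chronic disease patients",
      "farmers", "children", "elderly", "disabled people", "social organizations"]),
    ("X7", "policy tools",
     ["environmental-type", "demand-type", "supply-type"]),
    ("X8", "incentive measures",
     ["talent incentives", "tax incentives", "financial support", "government subsidies",
      "demonstration projects"]),
    ("X9", "related disciplines",
     ["public health", "medicine", "health economics", "sociology", "psychology",
      "nutrition", "behavioral science", "environmental science", "law"]),
]


def round2(x: Decimal | float | int | str) -> float:
    """Round half-up to two decimal places."""
    if not isinstance(x, Decimal):
        x = Decimal(str(x))
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VariableSchema:
    """The primary/secondary variable tree.

    ``primaries`` maps primary id -> human name; ``secondaries`` maps
    primary id -> ordered tuple of secondary ids ("X6:1", ...);
    ``secondary_names`` carries the indicator labels.
    """

    primaries: Mapping[str, str]
    secondaries: Mapping[str, tuple[str, ...]]
    secondary_names: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.primaries:
            raise ValueError("schema needs at least one primary variable")
        all_sec = [s for p in self.primaries for s in self.secondaries[p]]
        if len(set(all_sec)) != len(all_sec):
            raise ValueError("secondary ids must be unique")
        for p in self.primaries:
            if not self.secondaries.get(p):
                raise ValueError(f"primary {p!r} has no secondary indicators")

    @property
    def primary_ids(self) -> tuple[str, ...]:
        return tuple(self.primaries)

    @property
    def all_secondary_ids(self) -> tuple[str, ...]:
        return tuple(s for p in self.primaries for s in self.secondaries[p])

    @property
    def n_secondaries(self) -> int:
        return len(self.all_secondary_ids)

    def t(self, primary: str) -> int:
        """T(t): number of secondary indicators under a primary."""
        return len(self.secondaries[primary])


def _build_default() -> VariableSchema:
    prim, sec, names = {}, {}, {}
    for pid, pname, subs in _DEFAULT_PRIMARIES:
        prim[pid] = pname
        ids = tuple(f"{pid}:{j}" for j in range(1, len(subs) + 1))
        sec[pid] = ids
        for sid, sname in zip(ids, subs):
            names[sid] = sname
    return VariableSchema(primaries=prim, secondaries=sec, secondary_names=names)


DEFAULT_SCHEMA = _build_default()


def load_schema(config: str | Path | Mapping | None = None) -> VariableSchema:
    """Load a variable schema from YAML/JSON config, or the packaged
    nine-primary / 51-secondary default.

    Config format: mapping primary id -> {"name": ..., "secondaries":
    [label, ...]}.  A schema without exactly nine primaries is accepted
    for scoring individual primaries but warned about, since the PMC
    summation is defined over nine.
    """
    if config is None:
        return DEFAULT_SCHEMA
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
    prim, sec, names = {}, {}, {}
    for pid, spec_ in config.items():
        prim[pid] = str(spec_.get("name", pid))
        labels = list(spec_["secondaries"])
        ids = tuple(f"{pid}:{j}" for j in range(1, len(labels) + 1))
        sec[pid] = ids
        for sid, label in zip(ids, labels):
            names[sid] = str(label)
    schema = VariableSchema(primaries=prim, secondaries=sec, secondary_names=names)
    if len(schema.primary_ids) != 9:
        warnings.warn(
            f"schema has {len(schema.primary_ids)} primaries; the PMC index sum "
            "is defined over nine", stacklevel=2)
    return schema


@dataclass(frozen=True)
class PolicyCoding:
    """One policy's binary answers over every secondary indicator."""

    policy_id: str
    values: Mapping[str, int]

    def validate(self, schema: VariableSchema) -> None:
        for sid in schema.all_secondary_ids:
            if sid not in self.values:
                raise ValueError(f"policy {self.policy_id!r}: missing value for {sid}")
            if self.values[sid] not in (0, 1):
                raise ValueError(
                    f"policy {self.policy_id!r}: {sid} = {self.values[sid]!r} is not binary")


def score_primary(coding: PolicyCoding, schema: VariableSchema, t: str) -> float:
    """Mean of the binary secondaries under primary ``t``, rounded
    half-up to 2 dp (computed exactly in rational arithmetic)."""
    if t not in schema.primaries:
        raise KeyError(f"unknown primary {t!r}")
    total = Decimal(0)
    for sid in schema.secondaries[t]:
        if sid not in coding.values:
            raise ValueError(f"policy {coding.policy_id!r}: missing value for {sid}")
        v = coding.values[sid]
        if v not in (0, 1):
            raise ValueError(f"policy {coding.policy_id!r}: {sid} = {v!r} is not binary")
        total += v
    return round2(total / schema.t(t))


def pmc_index(primary_scores: Sequence[float]) -> float:
    """Sum of the nine primary scores, rounded half-up to 2 dp."""
    if len(primary_scores) != 9:
        raise ValueError(f"expected nine primary scores, got {len(primary_scores)}")
    for s in primary_scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"primary score {s} outside [0, 1]")
    return round2(sum(Decimal(str(s)) for s in primary_scores))


def classify(pmc: float) -> str:
    """Rating bins on the 2-dp PMC value: Poor [0,4), Acceptable [4,6),
    Excellent [6,8), Perfect [8,9]."""
    if not 0.0 <= pmc <= 9.0:
        raise ValueError(f"PMC index {pmc} outside [0, 9]")
    if pmc < 4.0:
        return "Poor"
    if pmc < 6.0:
        return "Acceptable"
    if pmc < 8.0:
        return "Excellent"
    return "Perfect"


def pmc_matrix(primary_scores: Sequence[float]) -> np.ndarray:
    """Row-major 3×3 arrangement [[X1,X2,X3],[X4,X5,X6],[X7,X8,X9]]."""
    if len(primary_scores) != 9:
        raise ValueError(f"expected nine primary scores, got {len(primary_scores)}")
    return np.asarray(primary_scores, dtype=float).reshape(3, 3)


@dataclass(frozen=True)
class PMCResult:
    """Scores for one policy: the nine primary means, the index, its
    rating and the 3×3 surface matrix."""

    policy_id: str
    primary_scores: Mapping[str, float]  # primary id -> 2-dp score
    pmc: float
    rating: str
    matrix: np.ndarray

    @property
    def score_vector(self) -> list[float]:
        return list(self.primary_scores.values())


def evaluate_policy(coding: PolicyCoding, schema: VariableSchema | None = None) -> PMCResult:
    """Full per-policy evaluation: primary means, PMC index, rating bin
    and surface matrix."""
    schema = schema or DEFAULT_SCHEMA
    coding.validate(schema)
    if len(schema.primary_ids) != 9:
        raise ValueError("the PMC index requires a nine-primary schema")
    scores = {p: score_primary(coding, schema, p) for p in schema.primary_ids}
    vec = [scores[p] for p in schema.primary_ids]
    pmc = pmc_index(vec)
    return PMCResult(policy_id=coding.policy_id, primary_scores=scores,
                     pmc=pmc, rating=classify(pmc), matrix=pmc_matrix(vec))


@dataclass(frozen=True)
class CohortSummary:
    """Cross-policy summary: 2-dp means per primary and of the index,
    plus competition ranks (1 = highest PMC; ties share the smaller
    rank, ordered first-seen)."""

    primary_means: Mapping[str, float]
    mean_pmc: float
    ranks: Mapping[str, int]


def cohort_summary(results: Sequence[PMCResult]) -> CohortSummary:
    if not results:
        raise ValueError("need at least one policy result")
    primaries = list(results[0].primary_scores)
    means = {
        p: round2(sum(Decimal(str(r.primary_scores[p])) for r in results) / len(results))
        for p in primaries
    }
    mean_pmc = round2(sum(Decimal(str(r.pmc)) for r in results) / len(results))
    ranks = {r.policy_id: 1 + sum(o.pmc > r.pmc for o in results) for r in results}
    return CohortSummary(primary_means=means, mean_pmc=mean_pmc, ranks=ranks)


def surface_export(result: PMCResult, grid_density: int = 33) -> np.ndarray:
    """Bilinear interpolation of the 3×3 matrix onto a grid_density²
    lattice for surface plotting; returns rows (x, y, z) with x, y on
    [0, 2] cell coordinates.  Corner values equal the matrix corners.
    """
    if grid_density < 3:
        raise ValueError("grid_density must be >= 3")
    m = result.matrix
    ax = np.linspace(0.0, 2.0, grid_density)
    rows = []
    for y in ax:
        i0 = min(int(y), 1)
        fy = y - i0
        for x in ax:
            j0 = min(int(x), 1)
            fx = x - j0
            z = ((1 - fy) * ((1 - fx) * m[i0, j0] + fx * m[i0, j0 + 1])
                 + fy * ((1 - fx) * m[i0 + 1, j0] + fx * m[i0 + 1, j0 + 1]))
            rows.append((x, y, z))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# CSV interfaces

def write_coding_csv(codings: Sequence[PolicyCoding], schema: VariableSchema,
                     path) -> None:
    """Write a binary coding matrix to a CSV path or open text stream."""
    cols = list(schema.all_secondary_ids)

    def _rows(fh):
        w = csv.writer(fh)
        w.writerow(["policy_id"] + cols)
        for c in codings:
            w.writerow([c.policy_id] + [c.values[s] for s in cols])

    if hasattr(path, "write"):
        _rows(path)
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            _rows(fh)


def read_coding_csv(path: str | Path, schema: VariableSchema | None = None
                    ) -> list[PolicyCoding]:
    """Read a binary coding matrix (rows = policies, columns = secondary
    ids); every schema column must be present."""
    schema = schema or DEFAULT_SCHEMA
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = set(reader.fieldnames or ())
        missing = [s for s in schema.all_secondary_ids if s not in cols]
        if missing:
            raise ValueError(f"coding CSV missing columns: {missing}")
        out = []
        for row in reader:
            vals = {s: int(row[s]) for s in schema.all_secondary_ids}
            coding = PolicyCoding(policy_id=row["policy_id"], values=vals)
            coding.validate(schema)
            out.append(coding)
    if not out:
        raise ValueError(f"no policy rows in {path}")
    return out


def results_table(results: Sequence[PMCResult]):
    """Table mirroring the standard PMC report layout: one column per
    policy plus a Mean column; rows X1..X9, PMC, Rank, Rating."""
    import pandas as pd

    summary = cohort_summary(results)
    primaries = list(results[0].primary_scores)
    data = {}
    for r in results:
        data[r.policy_id] = ([r.primary_scores[p] for p in primaries]
                             + [r.pmc, summary.ranks[r.policy_id], r.rating])
    data["Mean"] = ([summary.primary_means[p] for p in primaries]
                    + [summary.mean_pmc, "/", classify(summary.mean_pmc)])
    return pd.DataFrame(data, index=primaries + ["PMC", "Rank", "Rating"])
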