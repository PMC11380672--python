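"""Configuration, persistence, seeding and audit logging.

Everything stochastic in a run flows through :func:`derive_seed`, a hash-based
splitter from a single master seed, so that any run can be replayed
byte-identically from its manifest and so that changing one stage's draws
cannot perturb another's.
"""

from __future__ import annotations

import csv
import hashlib
import json

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable

import yaml

from .community import Community, CompatibilityMap, InputError, SpeciesPool

__all__ = [
    "derive_seed",
    "STAGE_LABELS",
    "AuditLog",
    "RunManifest",
    "load_config",
    "read_species_pool",
    "write_species_pool",
    "read_compatibility",
    "write_compatibility",
    "write_plan_csv",
    "read_plan_csv",
    "write_scores_csv",
    "read_scores_csv",
]

#: Fixed vocabulary of stochastic stages; each gets its own RNG substream.
STAGE_LABELS = frozenset(
    {
        "initial",
        "plated_choice",
        "offspring",
        "invasion_targets",
        "invader_identity",
        "landscape",
        "replicate",
    }
)


def derive_seed(master_seed: int, round_index: int, stage_label: str) -> int:
    """Deterministic child seed for one stage of one round.

    BLAKE2b over ``"master:round:stage"`` truncated to 31 bits — collision
    resistant over any realistic number of (round, stage) pairs and safely
    inside the range every RNG accepts.  Stage labels may carry a treatment
    qualifier, e.g. ``"selection/offspring"``; the base label must come from
    :data:`STAGE_LABELS`.
    """
    base = stage_label.rsplit("/", 1)[-1]
    if base not in STAGE_LABELS:
        raise InputError(f"unknown stage label {stage_label!r}")
    digest = hashlib.blake2b(
        f"{master_seed}:{round_index}:{stage_label}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class AuditLog:
    """Append-only record of every stochastic decision, serializable as JSONL.

    Records carry a logical sequence number rather than wall-clock time so
    that replaying a run reproduces the log byte-for-byte.
    """

    records: list[dict[str, Any]] = field(default_factory=list)

    def append(self, round_index: int, stage: str, **payload: Any) -> None:
        self.records.append(
            {"seq": len(self.records), "round": round_index, "stage": stage, **payload}
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


@dataclass
class RunManifest:
    """Everything needed to replay a run byte-identically."""

    config: dict[str, Any]
    master_seed: int
    software_version: str
    child_seeds: dict[str, int] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def record_file(self, path: str | Path) -> None:
        data = Path(path).read_bytes()
        self.files[str(path)] = hashlib.sha256(data).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path):
    """Read a YAML/JSON run config, applying defaults and rejecting unknown keys."""
    from .engine import SelectionConfig  # deferred: engine imports runio

    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise InputError(f"config root must be a mapping, got {type(payload).__name__}")
    landscape_path = payload.pop("landscape", None)
    known = set(SelectionConfig.__dataclass_fields__)
    unknown = sorted(set(payload) - known)
    if unknown:
        raise InputError(f"unknown config key(s): {', '.join(unknown)}")
    return SelectionConfig(**payload), landscape_path


# ---------------------------------------------------------------------------
# Tabular files.  Dialect: UTF-8, comma-separated, mandatory header, '.'
# decimal separator; floats serialized at repr precision for exact round-trips.
# ---------------------------------------------------------------------------

def read_species_pool(path: str | Path) -> SpeciesPool:
    """Two-column TSV ``acronym<TAB>display_name`` with a header line."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise InputError(f"{path}: empty species file")
    rows = [ln.split("\t") for ln in lines[1:] if ln.strip()]
    for i, row in enumerate(rows, start=2):
        if len(row) != 2:
            raise InputError(f"{path}: line {i}: expected 2 tab-separated fields")
    return SpeciesPool(
        species=tuple(r[0] for r in rows),
        display_names={r[0]: r[1] for r in rows},
    )


def write_species_pool(pool: SpeciesPool, path: str | Path) -> None:
    lines = ["acronym\tdisplay_name"]
    for s in pool.species:
        lines.append(f"{s}\t{pool.display_names.get(s, s)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_compatibility(path: str | Path, pool: SpeciesPool | None = None) -> CompatibilityMap:
    """Two-column TSV of forbidden acronym pairs (unordered; duplicates ignored)."""
    lines = Path(path).read_text().splitlines()
    pairs = []
    for i, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}: line {i}: expected 2 tab-separated fields")
        pairs.append((parts[0], parts[1]))
    return CompatibilityMap.from_pairs(pairs, pool)


def write_compatibility(cmap: CompatibilityMap, path: str | Path) -> None:
    lines = ["acronym_a\tacronym_b"]
    for pair in sorted(tuple(sorted(p)) for p in cmap.forbidden_pairs):
        lines.append(f"{pair[0]}\t{pair[1]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_plan_csv(communities: Iterable[Community], path: str | Path, pool: SpeciesPool) -> None:
    """Round-plan CSV: ``round,treatment,community_id,member_1..member_k``."""
    communities = list(communities)
    if not communities:
        raise InputError("cannot write an empty plan")
    k = communities[0].size()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["round", "treatment", "community_id"] + [f"member_{i+1}" for i in range(k)])
        for c in communities:
            if c.size() != k:
                raise InputError(
                    f"community {c.community_id}: size {c.size()} != plan size {k}"
                )
            w.writerow([c.round_index, c.treatment, c.community_id, *pool.sorted_members(c.members)])


def read_plan_csv(path: str | Path, pool: SpeciesPool, cmap: CompatibilityMap | None = None) -> list[Community]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InputError(f"{path}: empty plan file") from None
        member_cols = [h for h in header if h.startswith("member_")]
        if header[:3] != ["round", "treatment", "community_id"] or not member_cols:
            raise InputError(f"{path}: malformed plan header: {header}")
        k = len(member_cols)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3 + k:
                raise InputError(f"{path}: line {lineno}: expected {3 + k} fields, got {len(row)}")
            members = row[3:]
            pool.check_members(members)
            if len(set(members)) != k:
                raise InputError(f"{path}: line {lineno}: duplicate members {members}")
            if cmap is not None and not cmap.is_allowed(members):
                raise InputError(
                    f"{path}: line {lineno}: forbidden pair(s) {cmap.violations(members)}"
                )
            out.append(
                Community(
                    members=frozenset(members),
                    community_id=row[2],
                    round_index=int(row[0]),
                    treatment=row[1],
                )
            )
    return out


def write_scores_csv(rows: list[dict[str, Any]], path: str | Path, pool: SpeciesPool) -> None:
    """Score sheet: ``community_id,cod_sample,cod_control``, per-species CFU/ml
    columns, and a parallel ``inoc_<acronym>`` 0/1 block."""
    cols = ["community_id", "cod_sample", "cod_control"]
    cols += list(pool.species) + [f"inoc_{s}" for s in pool.species]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in rows:
            w.writerow([
                r["community_id"], repr(float(r["cod_sample"])), repr(float(r["cod_control"])),
                *[repr(float(r["counts"].get(s, 0.0))) for s in pool.species],
                *[int(s in r["inoculated"]) for s in pool.species],
            ])


def read_scores_csv(path: str | Path, pool: SpeciesPool) -> list[dict[str, Any]]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [s for s in pool.species if s not in fields]
        missing += [f"inoc_{s}" for s in pool.species if f"inoc_{s}" not in fields]
        if missing:
            raise InputError(f"{path}: missing column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    {
                        "community_id": row["community_id"],
                        "cod_sample": float(row["cod_sample"]),
                        "cod_control": float(row["cod_control"]),
                        "counts": {s: float(row[s]) for s in pool.species},
                        "inoculated": frozenset(
                            s for s in pool.species if row[f"inoc_{s}"] == "1"
                        ),
                    }
                )
            except (KeyError, ValueError) as exc:
                raise InputError(f"{path}: line {lineno}: {exc}") from exc
    return out
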