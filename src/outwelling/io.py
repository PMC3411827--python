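"""Shared CSV validation, schemas and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .isotopes import D13C_BOUNDS, D15N_BOUNDS

__all__ = ["SCHEMAS", "ValidationIssue", "ValidationReport", "validate_tables", "RunManifest"]

SCHEMAS: dict[str, dict] = {
    "sources": {
        "required": ["source", "estuary", "replicate", "d13C", "d15N"],
        "numeric": ["d13C", "d15N"],
    },
    "consumers": {
        "required": ["site_id", "distance_rank", "species", "tissue", "individual", "d13C", "d15N"],
        "numeric": ["distance_rank", "d13C", "d15N"],
    },
    "community": {
        "required": ["sample_id", "site_id", "location", "taxon", "count"],
        "numeric": ["count"],
    },
    "traits": {"required": ["taxon"], "numeric": []},
    "env": {
        "required": ["site_id", "location", "distance_rank"],
        "numeric": ["distance_rank"],
    },
}


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    row: int | None  # 0-based data row, None for table-level issues
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            lines = "\n".join(
                f"  {i.table}" + (f"[row {i.row}]" if i.row is not None else "") + f": {i.message}"
                for i in self.errors
            )
            raise ValueError(f"validation failed with {len(self.errors)} error(s):\n{lines}")


def _check_numeric(df: pd.DataFrame, table: str, cols, issues) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for row in bad:
            issues.append(
                ValidationIssue(table, int(row), "error", f"non-numeric value in {col!r}: {df.loc[row, col]!r}")
            )


def validate_tables(paths: dict[str, str | Path], *, allow_implausible: bool = False) -> ValidationReport:
    """Validate a bundle of CSVs against their schemas and key alignment.

    All violations are collected (not first-failure): missing columns,
    non-numeric fields, implausible delta values (warnings unless
    ``allow_implausible``), negative counts, and site_ids present in
    consumers/community but absent from env.
    """
    report = ValidationReport()
    issues = report.issues
    for name, path in paths.items():
        schema = SCHEMAS.get(name)
        path = Path(path)
        if not path.exists():
            issues.append(ValidationIssue(name, None, "error", f"file not found: {path}"))
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            issues.append(ValidationIssue(name, None, "error", f"unreadable CSV: {exc}"))
            continue
        report.tables[name] = df
        if schema is None:
            continue
        missing = [c for c in schema["required"] if c not in df.columns]
        for col in missing:
            issues.append(ValidationIssue(name, None, "error", f"missing required column {col!r}"))
        _check_numeric(df, name, schema["numeric"], issues)

    for name in ("sources", "consumers"):
        df = report.tables.get(name)
        if df is None or not {"d13C", "d15N"}.issubset(df.columns):
            continue
        c = pd.to_numeric(df["d13C"], errors="coerce")
        n = pd.to_numeric(df["d15N"], errors="coerce")
        out = (~c.between(*D13C_BOUNDS) & c.notna()) | (~n.between(*D15N_BOUNDS) & n.notna())
        severity = "warning"
        for row in df.index[out]:
            issues.append(
                ValidationIssue(
                    name,
                    int(row),
                    severity,
                    f"delta values ({df.loc[row, 'd13C']}, {df.loc[row, 'd15N']}) outside "
                    f"plausibility bounds d13C {D13C_BOUNDS}, d15N {D15N_BOUNDS}",
                )
            )

    comm = report.tables.get("community")
    if comm is not None and "count" in comm.columns:
        counts = pd.to_numeric(comm["count"], errors="coerce")
        for row in comm.index[counts < 0]:
            issues.append(ValidationIssue("community", int(row), "error", "negative count"))

    env = report.tables.get("env")
    if env is not None and "site_id" in env.columns:
        known = set(env["site_id"].astype(str))
        for name in ("consumers", "community"):
            df = report.tables.get(name)
            if df is None or "site_id" not in df.columns:
                continue
            orphans = sorted(set(df["site_id"].astype(str)) - known)
            for site in orphans:
                issues.append(
                    ValidationIssue(name, None, "error", f"site_id {site!r} absent from env table")
                )

    traits = report.tables.get("traits")
    if traits is not None and comm is not None and "taxon" in traits.columns and "taxon" in comm.columns:
        orphans = sorted(set(comm["taxon"]) - set(traits["taxon"]))
        if orphans:
            issues.append(
                ValidationIssue(
                    "community",
                    None,
                    "warning",
                    f"{len(orphans)} taxa missing from trait table (e.g. {orphans[:3]})",
                )
            )
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written alongside every pipeline run.

    Contains everything needed to re-run bit-identically: seeds,
    parameter echo, input checksums and the package version. Wall-clock
    timestamps are deliberately excluded so identical runs produce
    identical manifests.
    """

    seed: int
    parameters: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    package_version: str = ""
    config_hash: str = ""

    @classmethod
    def create(cls, seed: int, parameters: dict, input_paths: dict[str, str | Path]) -> "RunManifest":
        from . import __version__

        checksums = {name: _sha256(Path(p)) for name, p in sorted(input_paths.items())}
        blob = json.dumps({"seed": seed, "parameters": parameters}, sort_keys=True, default=str)
        return cls(
            seed=seed,
            parameters=parameters,
            input_checksums=checksums,
            package_version=__version__,
            config_hash=hashlib.sha256(blob.encode()).hexdigest(),
        )

    def write(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "parameters": self.parameters,
            "input_checksums": self.input_checksums,
            "package_version": self.package_version,
            "config_hash": self.config_hash,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
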