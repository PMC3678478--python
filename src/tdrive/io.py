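"""File schemas, configuration, and result serialization.

All tabular inputs and outputs are plain CSV/TSV with a header row;
randomized outputs carry a provenance header of ``#``-prefixed comment
lines (seed, config hash) that readers skip.  Genotype tokens are
normalized to the internal {WT, HET, TT} vocabulary: "+/+" -> WT,
"+/t" or "t/+" -> HET, "t/t" -> TT, case-insensitively.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .genetics import Genotype
from .incompatibility import LabCrossRecord
from .paternity import WildIndividual
from .popgen import MarkerGenotype

GENOTYPE_ALIASES = {
    "+/+": "WT", "wt": "WT", "w": "WT",
    "+/t": "HET", "t/+": "HET", "het": "HET",
    "t/t": "TT", "tt": "TT",
}


class SchemaError(ValueError):
    """A malformed input row or missing column."""


def normalize_genotype(token: str) -> Genotype:
    """Map a genotype string to the internal vocabulary."""
    s = str(token).strip().lower()
    name = GENOTYPE_ALIASES.get(s, s.upper())
    try:
        return Genotype(name)
    except ValueError:
        raise SchemaError(f"unknown genotype token {token!r}") from None


def _opt_int(v: Any) -> int | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return int(v)


# ---------------------------------------------------------------------------
# lab crosses
# ---------------------------------------------------------------------------

LAB_REQUIRED = ["cross_id", "sire_gt", "dam_gt", "litter_size_birth"]


def read_lab_crosses(path: str | Path, strict: bool = True) -> list[LabCrossRecord]:
    """Read a lab-cross CSV into validated records.

    Required columns: cross_id, sire_gt, dam_gt, litter_size_birth.
    Optional: red_scars, yellow_scars, n_het, n_wt, days_to_birth,
    n_weaned, experiment.  In strict mode any invalid row aborts with a
    per-row error report; otherwise bad rows are dropped.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in LAB_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            sire = normalize_genotype(row["sire_gt"])
            dam = normalize_genotype(row["dam_gt"])
            red = _opt_int(row.get("red_scars"))
            yellow = _opt_int(row.get("yellow_scars"))
            rec = LabCrossRecord(
                cross_id=str(row["cross_id"]),
                sire_gt=sire, dam_gt=dam,
                litter_size_birth=int(row["litter_size_birth"]),
                red_scars=red, yellow_scars=yellow,
                days_to_birth=float(row["days_to_birth"])
                if "days_to_birth" in df.columns and pd.notna(row["days_to_birth"])
                else None,
                n_weaned=_opt_int(row.get("n_weaned")),
                experiment=int(row.get("experiment", 1) or 1),
            )
            if "n_het" in df.columns and pd.notna(row["n_het"]):
                n_het, n_wt = int(row["n_het"]), int(row.get("n_wt", 0) or 0)
                if n_het < 0 or n_wt < 0:
                    raise SchemaError("negative pup counts")
                rec.pup_genotypes = (
                    [Genotype.HET] * n_het + [Genotype.WT] * n_wt
                )
            records.append(rec)
        except (SchemaError, ValueError) as e:
            errors.append(f"row {i}: {e}")
    if errors and strict:
        raise SchemaError("; ".join(errors))
    return records


def write_lab_crosses(records: Sequence[LabCrossRecord], path: str | Path,
                      provenance: dict | None = None) -> None:
    rows = []
    for r in records:
        pups = r.pup_genotypes or []
        rows.append({
            "cross_id": r.cross_id,
            "sire_gt": r.sire_gt.value,
            "dam_gt": r.dam_gt.value,
            "litter_size_birth": r.litter_size_birth,
            "red_scars": r.red_scars,
            "yellow_scars": r.yellow_scars,
            "n_het": sum(1 for g in pups if g == Genotype.HET) if pups else None,
            "n_wt": sum(1 for g in pups if g == Genotype.WT) if pups else None,
            "days_to_birth": r.days_to_birth,
            "n_weaned": r.n_weaned,
            "experiment": r.experiment,
        })
    _write_csv(pd.DataFrame(rows), path, provenance)


# ---------------------------------------------------------------------------
# wild population
# ---------------------------------------------------------------------------

def read_roster(path: str | Path) -> list[WildIndividual]:
    """Read the adult roster CSV (id, sex, genotype, first_seen, last_seen)."""
    df = pd.read_csv(path, comment="#")
    required = ["id", "sex", "genotype", "first_seen", "last_seen"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(WildIndividual(
            id=str(row["id"]),
            sex=str(row["sex"]).upper(),
            genotype=normalize_genotype(row["genotype"]),
            first_seen=date.fromisoformat(str(row["first_seen"])),
            last_seen=date.fromisoformat(str(row["last_seen"])),
        ))
    return out


def write_roster(roster: Sequence[WildIndividual], path: str | Path,
                 provenance: dict | None = None) -> None:
    df = pd.DataFrame(
        {"id": r.id, "sex": r.sex, "genotype": r.genotype.value,
         "first_seen": r.first_seen.isoformat(),
         "last_seen": r.last_seen.isoformat()}
        for r in roster
    )
    _write_csv(df, path, provenance)


def read_pups(path: str | Path) -> pd.DataFrame:
    """Read the pup parentage CSV (pup_id, litter_id, birth_date, dam_id, sire_id)."""
    df = pd.read_csv(path, comment="#")
    required = ["pup_id", "litter_id", "birth_date", "dam_id", "sire_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# marker genotypes
# ---------------------------------------------------------------------------

def read_marker_genotypes(path: str | Path) -> list[MarkerGenotype]:
    """Read a genotype CSV (individual, t_class, locus, allele1, allele2)."""
    df = pd.read_csv(path, comment="#")
    required = ["individual", "t_class", "locus", "allele1", "allele2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    return [
        MarkerGenotype(str(r["individual"]), normalize_genotype(r["t_class"]).value,
                       str(r["locus"]), str(r["allele1"]), str(r["allele2"]))
        for _, r in df.iterrows()
    ]


def write_marker_genotypes(genotypes: Sequence[MarkerGenotype], path: str | Path,
                           provenance: dict | None = None) -> None:
    df = pd.DataFrame(
        {"individual": g.individual, "t_class": g.t_class, "locus": g.locus,
         "allele1": g.allele1, "allele2": g.allele2}
        for g in genotypes
    )
    _write_csv(df, path, provenance)


# ---------------------------------------------------------------------------
# provenance, config, result bundle
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: str | Path,
               provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def provenance_header(seed: int | None, config: Any) -> dict:
    """Seed and config hash recorded at the top of generated files."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = str(dataclasses.asdict(config))
    else:
        payload = str(config)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
    return {"seed": seed, "config_sha256": digest}


@dataclass
class RunConfig:
    """Pipeline-wide switches with their defaults.

    m is the lethality-correction factor for the virtual-pup adjustment;
    bootstrap_B the number of bootstrap resamples; mc_permutations the
    Monte-Carlo size of exact tests; window_days the candidate-sire
    detection window before a litter's birth date.
    """

    m: float = 0.403
    bootstrap_B: int = 10_000
    mc_permutations: int = 100_000
    window_days: int = 30
    seed: int | None = None
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ResultBundle:
    """Named results plus provenance; serializes losslessly to JSON."""

    results: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"results": self.results, "provenance": self.provenance},
            indent=2, default=_jsonify, sort_keys=True,
        )
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ResultBundle":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        data = json.loads(text)
        return cls(results=data["results"], provenance=data["provenance"])


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Genotype):
        return obj.value
    if isinstance(obj, date):
        return obj.isoformat()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
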