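"""Tabular report writers, run configuration and manifest helpers.

All tabular outputs are TSV with a single header line preceded by
'#'-prefixed metadata lines, so reports diff cleanly and round-trip
through pandas.  BED-like interval inputs are 0-based half-open on disk
and converted to the package's 1-based closed convention at the reader
boundary (see :func:`bemux.burden.read_intervals_bed`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

import bemux
from bemux.guide_design import GuideCandidate
from bemux.outcomes import EditOutcome, StopSite

__all__ = [
    "RunConfig",
    "ConfigError",
    "write_report_tsv",
    "read_report_tsv",
    "guide_rows",
    "stop_site_rows",
    "write_manifest",
]


class ConfigError(ValueError):
    """A run configuration violates the schema."""


_SCHEMA = {
    "window": tuple,
    "extended_window": tuple,
    "allow_extended": bool,
    "include_rare_cbe": bool,
    "kataegis_min_run": int,
    "kataegis_max_distance": int,
    "flank": int,
    "max_mismatches": int,
    "seed": int,
    "out_dir": str,
}


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the anchored constants."""

    window: tuple[int, int] = (4, 8)
    extended_window: tuple[int, int] = (3, 9)
    allow_extended: bool = False
    include_rare_cbe: bool = False
    kataegis_min_run: int = 6
    kataegis_max_distance: int = 1000
    flank: int = 200
    max_mismatches: int = 4
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        self.window = tuple(self.window)
        self.extended_window = tuple(self.extended_window)
        self.validate()

    def validate(self) -> None:
        for key, typ in _SCHEMA.items():
            value = getattr(self, key)
            if not isinstance(value, typ):
                raise ConfigError(f"config key {key!r}: expected {typ.__name__}")
        lo, hi = self.window
        elo, ehi = self.extended_window
        if not (elo <= lo <= hi <= ehi):
            raise ConfigError("extended_window must contain window")
        for key in ("kataegis_min_run", "kataegis_max_distance", "flank"):
            if getattr(self, key) < 1:
                raise ConfigError(f"config key {key!r}: must be >= 1")
        if self.max_mismatches < 0:
            raise ConfigError("config key 'max_mismatches': must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window", "extended_window"):
            if key in data:
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report_tsv(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Write a TSV report with '#'-prefixed metadata lines before the header."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _fmt_offsets(offsets: Iterable[int]) -> str:
    return ",".join(str(o) for o in sorted(offsets))


def guide_rows(candidates: Sequence[GuideCandidate]) -> pd.DataFrame:
    """One row per guide candidate."""
    return pd.DataFrame(
        {
            "gene": [c.gene_id for c in candidates],
            "editor": [c.editor for c in candidates],
            "strand": [c.strand for c in candidates],
            "protospacer_start": [c.protospacer_start for c in candidates],
            "spacer": [c.spacer for c in candidates],
            "pam": [c.pam_seq for c in candidates],
            "target_offsets": [_fmt_offsets(c.target_offsets) for c in candidates],
            "substrate_offsets": [_fmt_offsets(c.substrate_offsets) for c in candidates],
            "changes": [
                ";".join(f"c.{x.position}{x.ref}>{x.alt}" for x in c.changes)
                for c in candidates
            ],
            "alt_codon": [c.alt_codon for c in candidates],
            "flags": [",".join(sorted(c.flags)) for c in candidates],
            "indel_risk": [int(c.indel_risk) for c in candidates],
        }
    )


def _consequence_summary(outcome: EditOutcome) -> str:
    return ";".join(
        f"{c.codon_index}:{c.codon_before}>{c.codon_after}:{c.consequence}"
        for c in outcome.consequences
    )


def stop_site_rows(sites: Sequence[StopSite], gene: str = "") -> pd.DataFrame:
    """One row per (stop site, guide); unguided sites get one row with no guide."""
    rows = []
    for s in sites:
        guides = s.guides or (None,)
        for g in guides:
            rows.append(
                {
                    "gene": gene or (g.gene_id if g else ""),
                    "codon_index": s.codon_index,
                    "codon": s.codon,
                    "strategy": s.stop_strategy,
                    "required_offsets": "|".join(
                        _fmt_offsets(sub) for sub in s.required_offsets
                    ),
                    "editor": g.editor if g else "",
                    "strand": g.strand if g else "",
                    "spacer": g.spacer if g else "",
                    "pam": g.pam_seq if g else "",
                    "target_offsets": _fmt_offsets(g.target_offsets) if g else "",
                    "flags": ",".join(sorted(g.flags)) if g else "",
                }
            )
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, config: RunConfig, extra: Mapping | None = None) -> None:
    manifest = {
        "package": "bemux",
        "version": bemux.__version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
        fh.write("\n")
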