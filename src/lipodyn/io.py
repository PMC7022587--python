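"""Plain-text file formats and run configuration.

Everything is tab-separated with explicit headers so fixtures stay
inspectable and diff-able:

* elastic scans: ``temperature_K  Q_invA  intensity  sigma``
* peak lists: ``peptide_id  start  end  charge  time_s  mz  intensity`` with
  ``time_s`` = -1 for the 0% control and -2 for the 80% control
* run configuration: YAML, round-tripping without loss.

mzML import is a documented extension point (write a converter to the peak
TSV schema); it is deliberately not part of the core.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .elastic import ElasticScan, ForceSegments, MsdSeries
from .envelope import TIME_CONTROL_0, Envelope
from .peptides import PeptideRecord

__all__ = [
    "read_fasta_sequence",
    "read_scan_table",
    "write_scan_table",
    "write_msd_series",
    "write_force_segments",
    "read_peak_table",
    "write_peak_table",
    "PeptideDataset",
    "RunConfig",
]

SCAN_COLUMNS = ["temperature_K", "Q_invA", "intensity", "sigma"]
PEAK_COLUMNS = ["peptide_id", "start", "end", "charge", "time_s", "mz", "intensity"]


def read_fasta_sequence(path: str | Path) -> str:
    """First record of a FASTA file as an upper-case residue string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def _validated_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_scan_table(path: str | Path) -> list[ElasticScan]:
    """Read elastic scans grouped by temperature, sorted by Q."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = _validated_numeric(df, SCAN_COLUMNS, path)
    scans = []
    for temp, grp in df.groupby("temperature_K", sort=True):
        grp = grp.sort_values("Q_invA")
        scans.append(
            ElasticScan(
                float(temp),
                grp["Q_invA"].to_numpy(),
                grp["intensity"].to_numpy(),
                grp["sigma"].to_numpy(),
            )
        )
    return scans


def write_scan_table(scans: list[ElasticScan], path: str | Path) -> None:
    rows = [
        (s.temperature, q, i, sg)
        for s in sorted(scans, key=lambda s: s.temperature)
        for q, i, sg in zip(s.q, s.intensity, s.sigma)
    ]
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_msd_series(series: MsdSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "temperature_K": series.temperature,
            "msd_A2": series.msd,
            "sigma_A2": series.msd_sigma,
            "valid_fraction": series.valid_fraction,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_force_segments(segments: ForceSegments, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "T_low_K": s.t_low,
                "T_high_K": s.t_high,
                "slope_A2_per_K": s.slope,
                "slope_stderr": s.slope_stderr,
                "force_constant_N_per_m": s.force_constant,
                "stderr_N_per_m": s.stderr,
                "flag": s.flag,
            }
            for s in segments.segments
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass(frozen=True)
class PeptideDataset:
    """Envelopes grouped per peptide, controls attached."""

    peptides: dict  # peptide_id -> PeptideRecord (sequence filled from FASTA)
    envelopes: dict  # peptide_id -> {time_s: Envelope}

    def times(self, peptide_id: str) -> list[float]:
        return sorted(t for t in self.envelopes[peptide_id] if t >= 0)


def read_peak_table(path: str | Path, sequence: str) -> PeptideDataset:
    """Read a peak-list TSV against its parent protein sequence.

    Duplicate (peptide, time, mz) rows are summed — the documented merge rule
    for peak lists concatenated across acquisitions.  Every peptide must have
    a 0% control; a missing 80% control is tolerated with a warning (the
    analysis then skips back-exchange correction).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = _validated_numeric(df, ["start", "end", "charge", "time_s", "mz", "intensity"], path)
    df = (
        df.groupby(["peptide_id", "start", "end", "charge", "time_s", "mz"], as_index=False)[
            "intensity"
        ].sum()
    )
    peptides: dict[str, PeptideRecord] = {}
    envelopes: dict[str, dict[float, Envelope]] = {}
    for (pid, start, end, charge), grp in df.groupby(["peptide_id", "start", "end", "charge"]):
        start, end, charge = int(start), int(end), int(charge)
        pep = PeptideRecord(sequence[start - 1 : end], start, end, charge)
        peptides[pid] = pep
        envelopes[pid] = {}
        for time, sub in grp.groupby("time_s"):
            sub = sub.sort_values("mz")
            envelopes[pid][float(time)] = Envelope(
                pid, charge, float(time), sub["mz"].to_numpy(), sub["intensity"].to_numpy()
            )
    for pid, envs in envelopes.items():
        if TIME_CONTROL_0 not in envs:
            raise ValueError(f"peptide {pid}: no 0% deuteration control in {path}")
        if -2.0 not in envs:
            warnings.warn(
                f"peptide {pid}: no 80% control; back-exchange correction disabled",
                stacklevel=2,
            )
    return PeptideDataset(peptides, envelopes)


def write_peak_table(
    envelopes: list[Envelope], peptides: dict[str, PeptideRecord], path: str | Path
) -> None:
    rows = []
    for env in envelopes:
        pep = peptides[env.peptide_id]
        for mz, inten in zip(env.mz, env.intensity):
            rows.append((env.peptide_id, pep.start, pep.end, env.charge, env.time, mz, inten))
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


@dataclass
class RunConfig:
    """Full-pipeline configuration; round-trips through YAML without loss."""

    out_dir: str = "lipodyn_run"
    seed: int = 17
    # elastic arm
    instrument: str = "IN13-like"
    i0: float = 1.0
    eins_noise_fraction: float = 0.0
    msd_force_constants: tuple[float, ...] = (1.0, 0.25, 0.15)
    breakpoints: tuple[float, ...] = (200.0, 250.0)
    msd_at_anchor: float = 0.05
    # HDX arm
    sequence_fasta: str | None = None  # None -> packaged apoA-I fixture
    n_peptides: int = 20
    mean_peptide_length: int = 12
    pD: float = 7.2
    temperature_K: float = 273.15
    times_s: tuple[float, ...] = (30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0)
    back_exchange_fraction: float = 0.12
    hdx_noise_fraction: float = 0.0
    dimer_pf: float = 100.0
    monomer_pf: float = 2.0
    dimer_weight: float = 2 / 3
    # algorithm toggles
    abundance_cutoff: float = 0.75
    assignment_seed: int = 17
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(fields)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, val in data.items():
            if isinstance(val, list):
                data[key] = tuple(val)
        return cls(**data)
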