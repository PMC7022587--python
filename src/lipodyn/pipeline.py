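"""End-to-end pipeline: simulate (or load) -> fit -> pool -> residue map.

``analyze_peptide`` turns one peptide's envelopes into per-population uptake
curves, stretched-exponential fits and protection factors;
``run_pipeline`` drives both experiment arms from a :class:`RunConfig`,
writing every table in the package's own TSV formats plus a JSON fit report
and a run log recording versions, seeds and thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .elastic import bin_ramp, fit_force_constants, fit_msd_series
from .envelope import (
    TIME_CONTROL_0,
    TIME_CONTROL_80,
    TimeCourse,
    centroid,
    compute_di,
    deconvolve_bimodal,
    relative_abundance,
)
from .instruments import get_instrument
from .intrinsic import ExchangeConditions, average_rc_rate, intrinsic_rates
from .io import (
    PeptideDataset,
    RunConfig,
    write_force_segments,
    write_msd_series,
    write_peak_table,
    write_scan_table,
)
from .isotopes import D_MASS_SHIFT
from .kinetics import (
    PeptidePf,
    assign_residue_pf,
    build_pf_chart,
    classify_pf,
    fit_biphasic,
    pool_peptides,
    protection_factor,
)
from .peptides import count_exchangeable
from .simulate import HdxTruth, MsdModel, apoa1_sequence, digest_protein, make_elastic_dataset, make_hdx_dataset

__all__ = ["analyze_peptide", "analyze_dataset", "run_pipeline"]

log = logging.getLogger("lipodyn")


def analyze_peptide(
    dataset: PeptideDataset, peptide_id: str, cond: ExchangeConditions, seed: int = 0
) -> tuple[TimeCourse, PeptidePf]:
    """Deconvolve, correct and fit one peptide's HDX time course.

    Returns the per-population :class:`TimeCourse` (back-exchange-corrected
    DI) and the pooled-fit summary (:class:`PeptidePf`) holding the phase
    fits and protection factors of each population.
    """
    pep = dataset.peptides[peptide_id]
    envs = dataset.envelopes[peptide_id]
    n_exch = count_exchangeable(pep)
    ref0 = envs[TIME_CONTROL_0]
    cent0 = centroid(ref0)
    have80 = TIME_CONTROL_80 in envs
    cent80 = centroid(envs[TIME_CONTROL_80]) if have80 else None

    times = dataset.times(peptide_id)
    pairs = [(t, deconvolve_bimodal(envs[t], ref0, n_exch)) for t in times]
    abund = relative_abundance(pairs)

    def corrected(cent_mz: float) -> float:
        if have80:
            return compute_di(cent_mz, cent0, cent80, pep.charge, n_exch).di
        return (cent_mz - cent0) * pep.charge / D_MASS_SHIFT  # uncorrected fallback

    di_slow = np.array([corrected(p.slow.centroid_mz) for _, p in pairs])
    di_fast = np.array([corrected(p.fast.centroid_mz) for _, p in pairs])
    is_bimodal = any(p.is_bimodal for _, p in pairs)
    back_ex = (
        compute_di(cent0, cent0, cent80, pep.charge, n_exch).back_exchange_percent
        if have80
        else float("nan")
    )
    course = TimeCourse(
        peptide_id, n_exch, np.array(times), di_slow, di_fast, abund.ratio, is_bimodal, back_ex
    )

    k_rc, _ = average_rc_rate(intrinsic_rates(pep, cond))
    t_arr = np.array(times)
    populations, pfs = {}, {}
    labels = ("slow", "fast") if is_bimodal else ("all",)
    for label in labels:
        di = di_slow if label in ("slow", "all") else di_fast
        fitres = fit_biphasic(t_arr, di, n_exch, seed=seed)
        populations[label] = fitres
        pfs[label] = tuple(protection_factor(ph.rate, k_rc) for ph in fitres.phases)
    summary = PeptidePf(pep, is_bimodal, abund.ratio, populations, pfs, abund.major_is_slow)
    return course, summary


def analyze_dataset(
    dataset: PeptideDataset, cond: ExchangeConditions, seed: int = 0
) -> tuple[list[TimeCourse], list[PeptidePf]]:
    courses, summaries = [], []
    for pid in sorted(dataset.peptides):
        course, summary = analyze_peptide(dataset, pid, cond, seed=seed)
        courses.append(course)
        summaries.append(summary)
    return courses, summaries


def _uniform_pf(sequence: str, value: float) -> np.ndarray:
    pf = np.full(len(sequence), float(value))
    pf[[i for i, aa in enumerate(sequence) if aa == "P"]] = np.nan
    return pf


def run_pipeline(config: RunConfig) -> Path:
    """Simulate both arms, fit everything, write all outputs; deterministic."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_lines = [
        f"lipodyn {__version__}",
        f"seed={config.seed} assignment_seed={config.assignment_seed}",
        f"abundance_cutoff={config.abundance_cutoff}",
    ]

    # --- elastic arm ---
    cfg = get_instrument(config.instrument)
    if len(config.msd_force_constants) != len(config.breakpoints) + 1:
        raise ValueError(
            "eins stage: need one force constant per temperature segment "
            f"({len(config.breakpoints) + 1}), got {len(config.msd_force_constants)}"
        )
    model = MsdModel(
        tuple(config.breakpoints), tuple(config.msd_force_constants), config.msd_at_anchor
    )
    scans, _, _ = make_elastic_dataset(
        cfg, model, i0=config.i0, noise_fraction=config.eins_noise_fraction, seed=config.seed
    )
    write_scan_table(scans, out / "elastic_scans.tsv")
    if cfg.ramp is not None:
        scans = bin_ramp(scans, cfg.ramp.bin_width_K)
    series = fit_msd_series(scans, cfg)
    segments = fit_force_constants(series, tuple(config.breakpoints))
    write_msd_series(series, out / "msd_series.tsv")
    write_force_segments(segments, out / "force_segments.tsv")
    log_lines.append(f"eins: instrument={cfg.name} scans={len(scans)}")

    # --- HDX arm ---
    from .io import read_fasta_sequence, read_peak_table

    sequence = (
        apoa1_sequence() if config.sequence_fasta is None else read_fasta_sequence(config.sequence_fasta)
    )
    peptides = digest_protein(
        sequence, config.mean_peptide_length, config.n_peptides, seed=config.seed
    )
    cond = ExchangeConditions(pD=config.pD, temperature=config.temperature_K)
    truth = HdxTruth(
        sequence,
        tuple(peptides),
        {
            "dimer": _uniform_pf(sequence, config.dimer_pf),
            "monomer": _uniform_pf(sequence, config.monomer_pf),
        },
        {"dimer": config.dimer_weight, "monomer": 1.0 - config.dimer_weight},
        conditions=cond,
        times=tuple(config.times_s),
        back_exchange_fraction=config.back_exchange_fraction,
        seed=config.seed,
    )
    envelopes = make_hdx_dataset(truth, noise_fraction=config.hdx_noise_fraction)
    pep_by_id = {p.peptide_id: p for p in peptides}
    write_peak_table(envelopes, pep_by_id, out / "hdx_peaks.tsv")
    dataset = read_peak_table(out / "hdx_peaks.tsv", sequence)  # closed round trip

    courses, summaries = analyze_dataset(dataset, cond, seed=config.seed)
    report = []
    for course, summ in zip(courses, summaries):
        entry = {
            "peptide": summ.peptide.peptide_id,
            "n_exch": course.n_exch,
            "is_bimodal": summ.is_bimodal,
            "relative_abundance": summ.relative_abundance,
            "back_exchange_percent": course.back_exchange_percent,
            "populations": {},
        }
        for label, fitres in summ.populations.items():
            entry["populations"][label] = {
                "phases": [
                    {
                        "n_sites": ph.n_sites,
                        "rate_per_s": ph.rate,
                        "beta": ph.beta,
                        "pf": pf,
                        "class": classify_pf(pf),
                    }
                    for ph, pf in zip(fitres.phases, summ.pf[label])
                ],
                "rss": fitres.rss,
            }
        report.append(entry)
    (out / "fit_report.json").write_text(json.dumps(report, indent=1))

    dimer_pool, monomer_pool = pool_peptides(summaries, cutoff=config.abundance_cutoff)
    dimer_map = assign_residue_pf(dimer_pool, sequence, seed=config.assignment_seed)
    monomer_map = assign_residue_pf(monomer_pool, sequence, seed=config.assignment_seed)
    chart = build_pf_chart(dimer_map, monomer_map)
    chart.to_csv(out / "pf_chart.tsv", sep="\t", index=False, float_format="%.10g")
    rows = []
    for pool_name, pool_map in (("dimer", dimer_map), ("monomer", monomer_map)):
        for e in pool_map.entries:
            rows.append((pool_name, e.position, e.residue, e.pf, e.color, e.status))
    import pandas as pd

    pd.DataFrame(
        rows, columns=["pool", "residue_index", "residue", "pf", "class", "status"]
    ).to_csv(out / "pf_map.tsv", sep="\t", index=False, float_format="%.10g")
    log_lines.append(
        f"hdx: peptides={len(peptides)} dimer_conflicts={len(dimer_map.conflicts)} "
        f"monomer_conflicts={len(monomer_map.conflicts)}"
    )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
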