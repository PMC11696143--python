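"""Readers and writers for the FASTA/TSV dialects the pipeline consumes.

All written tables report element coordinates 1-based inclusive and carry a
header comment naming that convention; in-memory objects use 0-based
half-open offsets.  Readers are tolerant of comment lines and line-wrapped
FASTA.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from fbescan.binding import HillFit, ITCExperiment, OneSiteParams, TitrationSeries
from fbescan.motifs import ElementMatch, normalize_sequence
from fbescan.pairs import AdjacentPair, PairSummary
from fbescan.profiles import ExpressionProfile, resample_to_grid
from fbescan.records import PeakRecord

__all__ = [
    "read_peak_fasta",
    "write_peak_fasta",
    "read_peak_metadata",
    "write_peak_metadata",
    "write_matches_tsv",
    "read_matches_tsv",
    "write_pairs_tsv",
    "write_pair_summary_tsv",
    "read_titration_tsv",
    "write_titration_tsv",
    "write_hill_fit_tsv",
    "read_itc_tsv",
    "write_itc_tsv",
    "write_one_site_params_tsv",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "write_normalized_profiles_tsv",
    "write_manifest",
]

COORD_COMMENT = "# coordinates: 1-based inclusive"


# ---------------------------------------------------------------------------
# FASTA + peak metadata


def read_peak_fasta(path: str | Path) -> dict[str, str]:
    """Peak sequences keyed by record id, normalized to uppercase RNA.

    Duplicate ids and empty records are rejected by name; DNA-alphabet and
    mixed-case input parses unchanged in meaning (T mapped to U).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate peak id in FASTA: {rec.id!r}")
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"empty record in FASTA: {rec.id!r}")
        seqs[rec.id] = normalize_sequence(raw)
    return seqs


def write_peak_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_peak_metadata(path: str | Path, sequences: dict[str, str]) -> list[PeakRecord]:
    """Join a metadata TSV onto FASTA sequences by peak_id.

    Expected columns: peak_id (required), gene_id, region, wt_fpkm,
    y479a_fpkm.  Missing optional columns are tolerated with a warning; a
    metadata row whose peak is absent from the FASTA is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "peak_id" not in df.columns:
        raise ValueError("metadata must contain a peak_id column")
    unknown = sorted(set(df["peak_id"].astype(str)) - set(sequences))
    if unknown:
        raise KeyError(f"metadata peaks absent from FASTA: {unknown}")
    for col in ("gene_id", "region", "wt_fpkm", "y479a_fpkm"):
        if col not in df.columns:
            warnings.warn(f"metadata missing column {col!r}", stacklevel=2)

    records = []
    for row in df.itertuples(index=False):
        pid = str(row.peak_id)
        y = getattr(row, "y479a_fpkm", None)
        records.append(
            PeakRecord(
                peak_id=pid,
                gene_id=str(getattr(row, "gene_id", "")),
                region=str(getattr(row, "region", "")),
                sequence=sequences[pid],
                wt_height=float(getattr(row, "wt_fpkm", 0.0)),
                y479a_height=None if y is None or pd.isna(y) else float(y),
            )
        )
    return records


def write_peak_metadata(path: str | Path, peaks: Sequence[PeakRecord]) -> None:
    df = pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "gene_id": [p.gene_id for p in peaks],
            "region": [p.region for p in peaks],
            "wt_fpkm": [p.wt_height for p in peaks],
            "y479a_fpkm": [p.y479a_height for p in peaks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scanner / pair tables


def write_matches_tsv(path: str | Path, matches: Sequence[ElementMatch]) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT + "\n")
        df = pd.DataFrame(
            {
                "peak_id": [m.peak_id for m in matches],
                "class": [m.fbe_class for m in matches],
                "start_1based": [m.start + 1 for m in matches],
                "length": [m.length for m in matches],
                "matched": [m.matched for m in matches],
            }
        )
        df.to_csv(fh, sep="\t", index=False)


def read_matches_tsv(path: str | Path) -> list[ElementMatch]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ElementMatch(
            peak_id=str(pid),
            fbe_class=str(cls),
            start=int(start1) - 1,
            length=int(length),
            matched=str(matched),
        )
        for pid, cls, start1, length, matched in zip(
            df["peak_id"], df["class"], df["start_1based"], df["length"], df["matched"]
        )
    ]


def write_pairs_tsv(
    path: str | Path,
    pairs: Sequence[AdjacentPair],
    peaks: dict[str, PeakRecord] | None = None,
) -> None:
    """Pair table mirroring the published adjacent-site listing."""
    peaks = peaks or {}
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT + "\n")
        df = pd.DataFrame(
            {
                "peak_id": [p.peak_id for p in pairs],
                "gene_id": [peaks[p.peak_id].gene_id if p.peak_id in peaks else "" for p in pairs],
                "region": [peaks[p.peak_id].region if p.peak_id in peaks else "" for p in pairs],
                "class_5p": [p.element_5p.fbe_class for p in pairs],
                "start_5p": [p.element_5p.start + 1 for p in pairs],
                "class_3p": [p.element_3p.fbe_class for p in pairs],
                "start_3p": [p.element_3p.start + 1 for p in pairs],
                "distance": [p.distance for p in pairs],
            }
        )
        df.to_csv(fh, sep="\t", index=False)


def write_pair_summary_tsv(path: str | Path, summary: PairSummary) -> None:
    rows = [
        ("n_peaks_with_pairs", summary.n_peaks_with_pairs),
        ("n_unique_genes", summary.n_unique_genes),
    ]
    rows += [(f"region:{k}", v) for k, v in sorted(summary.region_breakdown.items())]
    rows += [(f"second_class:{k}", v) for k, v in sorted(summary.class_breakdown.items())]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# titrations / ITC


def read_titration_tsv(path: str | Path, rna_label: str = "") -> TitrationSeries:
    df = pd.read_csv(path, sep="\t", comment="#").sort_values("concentration_nM")
    return TitrationSeries(
        concentrations=df["concentration_nM"].to_numpy(float),
        fraction_bound=df["fraction_bound"].to_numpy(float),
        rna_label=rna_label,
    )


def write_titration_tsv(path: str | Path, series: TitrationSeries) -> None:
    pd.DataFrame(
        {
            "concentration_nM": series.concentrations,
            "fraction_bound": series.fraction_bound,
        }
    ).to_csv(path, sep="\t", index=False)


def write_hill_fit_tsv(path: str | Path, fit: HillFit) -> None:
    pd.DataFrame(
        {
            "parameter": ["kd_app_nM", "hill", "bmax"],
            "estimate": [fit.kd_app, fit.hill, fit.bmax],
            "stderr": [
                fit.fit_errors.get("kd_app", np.nan),
                fit.fit_errors.get("hill", np.nan),
                fit.fit_errors.get("bmax", np.nan),
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_itc_tsv(path: str | Path) -> ITCExperiment:
    """ITC TSV: geometry in '# key = value' comments, one heat per row."""
    meta: dict[str, float] = {}
    heats: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = (s.strip() for s in body.split("=", 1))
                    try:
                        meta[k] = float(v)
                    except ValueError:
                        pass
                continue
            if line.lower().startswith("heat"):
                continue
            heats.append(float(line.split("\t")[-1]))
    required = ("cell_conc_uM", "syringe_conc_uM")
    for k in required:
        if k not in meta:
            raise ValueError(f"ITC TSV missing geometry comment {k!r}")
    return ITCExperiment(
        cell_conc=meta["cell_conc_uM"],
        syringe_conc=meta["syringe_conc_uM"],
        cell_volume=meta.get("cell_volume_uL", 200.0),
        injection_volume=meta.get("injection_volume_uL", 2.0),
        n_injections=len(heats),
        temperature=meta.get("temperature_K", 293.15),
        heats=np.array(heats),
    )


def write_itc_tsv(path: str | Path, exp: ITCExperiment) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_conc_uM = {exp.cell_conc}\n")
        fh.write(f"# syringe_conc_uM = {exp.syringe_conc}\n")
        fh.write(f"# cell_volume_uL = {exp.cell_volume}\n")
        fh.write(f"# injection_volume_uL = {exp.injection_volume}\n")
        fh.write(f"# temperature_K = {exp.temperature}\n")
        fh.write("heat_kJ_per_mol\n")
        for h in np.asarray(exp.heats):
            fh.write(f"{float(h)!r}\n")


def write_one_site_params_tsv(path: str | Path, params: OneSiteParams) -> None:
    pd.DataFrame(
        {
            "parameter": ["N_sites", "kd_app_uM", "dH_kJ_mol", "dG_kJ_mol", "minus_TdS_kJ_mol"],
            "estimate": [params.N, params.kd_app, params.dH, params.dG, params.minus_TdS],
            "stderr": [
                params.fit_errors.get("N", np.nan),
                params.fit_errors.get("kd_app", np.nan),
                params.fit_errors.get("dH", np.nan),
                np.nan,
                np.nan,
            ],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression profiles


def read_profiles_tsv(path: str | Path) -> dict[str, ExpressionProfile]:
    """Long-format profiles (gonad_id, genotype, position_um, intensity).

    Each gonad's profile is resampled onto the common 1-µm grid over
    0-100 µm by linear interpolation, then stacked per genotype.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, ExpressionProfile] = {}
    for genotype, gdf in df.groupby("genotype"):
        rows = []
        grid = None
        for _, gonad in gdf.groupby("gonad_id"):
            grid, resampled = resample_to_grid(
                gonad["position_um"].to_numpy(float),
                gonad["intensity"].to_numpy(float),
            )
            rows.append(resampled)
        out[str(genotype)] = ExpressionProfile(
            genotype=str(genotype), positions=grid, intensities=np.vstack(rows)
        )
    return out


def write_profiles_tsv(path: str | Path, profiles: Sequence[ExpressionProfile]) -> None:
    frames = []
    for prof in profiles:
        for g in range(prof.n_gonads):
            frames.append(
                pd.DataFrame(
                    {
                        "gonad_id": f"{prof.genotype}_g{g:03d}",
                        "genotype": prof.genotype,
                        "position_um": prof.positions,
                        "intensity": prof.intensities[g],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_normalized_profiles_tsv(path: str | Path, profiles) -> None:
    frames = []
    for prof in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "genotype": prof.genotype,
                    "position_um": prof.positions,
                    "mean": prof.mean,
                    "ci_low": prof.ci_low,
                    "ci_high": prof.ci_high,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run manifests


def write_manifest(path: str | Path, config: dict) -> None:
    """Record the full effective configuration of a run (reproducibility contract)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, default_flow_style=False, sort_keys=True)
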