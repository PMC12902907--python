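"""Readers and writers for count tables, frequency tables and results.

Conventions: UTF-8 CSV (TSV for ``.tsv`` paths), ``#``-prefixed metadata
comment lines of the form ``# key = value`` at the top of every written
file, and atomic writes (temp file then rename) so a crashed run never
leaves a truncated table behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import PopulationFrequencies, SampleCounts

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "read_frequencies",
    "write_frequencies",
    "write_estimates",
    "write_truth",
    "read_metadata",
    "samples_from_long",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent or Path("."), prefix=f".{path.name}.", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _render(df: pd.DataFrame, sep: str, meta: dict) -> str:
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    body = df.to_csv(index=False, sep=sep)
    return "\n".join(lines) + ("\n" if lines else "") + body


def _meta(**extra) -> dict:
    return {"ednamix_version": __version__, **extra}


def read_metadata(path) -> dict:
    """Parse the ``# key = value`` comment header of a written file."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
    return meta


def samples_from_long(
    df: pd.DataFrame,
    *,
    sample_col: str = "sample_id",
    haplotype_col: str = "haplotype_id",
    reads_col: str = "reads",
    replicate_col: str | None = "replicate",
    haplotype_ids: Sequence[str] | None = None,
) -> list[SampleCounts]:
    """Convert a long-format count table to aligned SampleCounts.

    Every (sample, replicate) pair becomes one :class:`SampleCounts` whose
    ``replicate_group`` is the sample id; missing (sample, haplotype)
    pairs count as zero reads. The haplotype index is the sorted set of
    observed ids unless ``haplotype_ids`` fixes it.
    """
    for col in (sample_col, haplotype_col, reads_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    has_rep = replicate_col is not None and replicate_col in df.columns
    reads = pd.to_numeric(df[reads_col], errors="raise")
    if (reads < 0).any():
        rows = df.index[reads < 0].tolist()
        raise ValueError(f"negative read counts at table rows {rows[:5]}")
    if not np.allclose(reads, np.rint(reads)):
        rows = df.index[reads != np.rint(reads)].tolist()
        raise ValueError(f"non-integer read counts at table rows {rows[:5]}")

    key_cols = [sample_col, haplotype_col] + ([replicate_col] if has_rep else [])
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].tolist()
        raise ValueError(
            f"duplicate count rows for key {tuple(first)} "
            f"(table rows {df.index[dup].tolist()[:5]})"
        )

    if haplotype_ids is None:
        # first-appearance order keeps written tables round-trippable
        haplotype_ids = tuple(dict.fromkeys(df[haplotype_col].astype(str)))
    else:
        haplotype_ids = tuple(str(h) for h in haplotype_ids)
        unknown = set(df[haplotype_col].astype(str)) - set(haplotype_ids)
        if unknown:
            raise ValueError(
                f"haplotypes {sorted(unknown)} not in the provided index"
            )
    hap_pos = {h: i for i, h in enumerate(haplotype_ids)}

    samples = []
    group_cols = [sample_col, replicate_col] if has_rep else [sample_col]
    for key, sub in df.groupby(group_cols, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        counts = np.zeros(len(haplotype_ids), dtype=np.int64)
        idx = [hap_pos[str(h)] for h in sub[haplotype_col]]
        counts[idx] = np.rint(sub[reads_col].to_numpy()).astype(np.int64)
        site = str(key[0])
        if has_rep and len(key) > 1:
            label = str(key[1])
            # replicate label may repeat the site id (single-replicate
            # tables) or already embed it; avoid doubling the prefix
            if label in (site, ""):
                sample_id = site
            elif label.startswith(f"{site}_"):
                sample_id = label
            else:
                sample_id = f"{site}_{label}"
        else:
            sample_id = site
        samples.append(
            SampleCounts(
                sample_id=sample_id,
                haplotype_ids=haplotype_ids,
                read_counts=counts,
                replicate_group=site,
            )
        )
    return samples


def read_counts_table(
    path,
    format: str = "auto",
    haplotype_ids: Sequence[str] | None = None,
) -> list[SampleCounts]:
    """Read a CSV/TSV count table in long or wide orientation.

    Long tables have columns ``sample_id, [replicate,] haplotype_id,
    reads``; wide tables have one row per sample (first column the sample
    id, remaining columns one per haplotype). ``format="auto"`` sniffs the
    orientation from the header. Zero-read samples are retained.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if format == "auto":
        cols = set(df.columns)
        format = (
            "long"
            if {"sample_id", "haplotype_id", "reads"} <= cols
            else "wide"
        )
    if format == "long":
        return samples_from_long(df, haplotype_ids=haplotype_ids)
    if format != "wide":
        raise ValueError("format must be 'long', 'wide' or 'auto'")
    if df.shape[1] < 2:
        raise ValueError("wide table needs a sample column plus haplotypes")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"ragged/missing values at table rows {bad[:5]}")
    sample_ids = df.iloc[:, 0].astype(str)
    if sample_ids.duplicated().any():
        dups = sample_ids[sample_ids.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids {dups[:5]}")
    hap_ids = tuple(str(c) for c in df.columns[1:])
    if haplotype_ids is not None and tuple(haplotype_ids) != hap_ids:
        raise ValueError("wide table columns do not match expected index")
    out = []
    for _, row in df.iterrows():
        counts = row.iloc[1:].to_numpy()
        if np.any(pd.to_numeric(counts) < 0):
            raise ValueError(
                f"negative read counts in sample {row.iloc[0]!r}"
            )
        out.append(
            SampleCounts(
                sample_id=str(row.iloc[0]),
                haplotype_ids=hap_ids,
                read_counts=pd.to_numeric(counts),
            )
        )
    return out


def write_counts_table(
    samples: Sequence[SampleCounts], path, format: str = "long", **meta
) -> None:
    """Write SampleCounts as a long or wide table with metadata header."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to write")
    sep = _sep_for(path)
    if format == "long":
        rows = []
        for s in samples:
            site = s.replicate_group or s.sample_id
            label = (
                s.sample_id[len(site) + 1 :]
                if s.sample_id.startswith(f"{site}_")
                else s.sample_id
            )
            for h, c in zip(s.haplotype_ids, s.read_counts):
                rows.append(
                    {
                        "sample_id": site,
                        "replicate": label,
                        "haplotype_id": h,
                        "reads": int(c),
                    }
                )
        df = pd.DataFrame(rows)
    elif format == "wide":
        df = pd.DataFrame(
            [s.read_counts for s in samples],
            columns=list(samples[0].haplotype_ids),
        )
        df.insert(0, "sample_id", [s.sample_id for s in samples])
    else:
        raise ValueError("format must be 'long' or 'wide'")
    _atomic_write(path, _render(df, sep, _meta(**meta)))


def read_frequencies(path) -> PopulationFrequencies:
    """Read a two-column (haplotype_id, frequency) table."""
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if not {"haplotype_id", "frequency"} <= set(df.columns):
        raise ValueError(
            "frequency table needs 'haplotype_id' and 'frequency' columns"
        )
    meta = read_metadata(path)
    ploidy = meta.get("ploidy", "1")
    return PopulationFrequencies(
        haplotype_ids=tuple(df["haplotype_id"].astype(str)),
        probs=df["frequency"].to_numpy(dtype=float),
        locus_label=meta.get("locus_label", "locus"),
        ploidy=None if ploidy in ("None", "unknown") else int(ploidy),
        metadata=meta,
    )


def write_frequencies(pi: PopulationFrequencies, path, **meta) -> None:
    """Write a frequency vector as a two-column table with metadata."""
    df = pd.DataFrame(
        {
            "haplotype_id": list(pi.haplotype_ids),
            "frequency": np.asarray(pi.probs, dtype=float),
        }
    )
    header = _meta(
        locus_label=pi.locus_label,
        ploidy=pi.ploidy,
        **{k: v for k, v in pi.metadata.items()},
        **meta,
    )
    _atomic_write(path, _render(df, _sep_for(path), header))


def write_estimates(frame: pd.DataFrame, path, **meta) -> None:
    """Write a per-sample estimates table with metadata header."""
    _atomic_write(path, _render(frame, _sep_for(path), _meta(**meta)))


def write_truth(truth: pd.DataFrame, path, **meta) -> None:
    """Write a simulation ground-truth table with metadata header."""
    _atomic_write(path, _render(truth, _sep_for(path), _meta(**meta)))
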