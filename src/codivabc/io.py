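"""Input/output: manifests, FASTA studies, statistic tables, configuration.

A study on disk is a manifest TSV assigning every sequence ID to a taxon
pair and to one of the two populations flanking a barrier, plus one or more
FASTA files holding the aligned sequences.  Locus-type rate multipliers
default to 20 for mtDNA and 1 for cpDNA/ITS loci when the manifest omits
them.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
from Bio import SeqIO

from .data import TaxonPair, encode_sequence
from .distances import SaturationError, distance_summary
from .stats import PAIR_STAT_NAMES, STAT_LAYOUT_VERSION, pair_summary_vector

__all__ = [
    "ManifestError", "read_manifest", "read_study", "stats_table",
    "write_stats_table", "read_config", "DEFAULT_RATE_MULTIPLIERS",
]

MANIFEST_COLUMNS = ("pair_id", "barrier_id", "fasta_path", "sequence_id", "population")

#: rate multiplier by locus type when the manifest has no explicit column
DEFAULT_RATE_MULTIPLIERS = {"mtDNA": 20.0, "cpDNA": 1.0, "ITS": 1.0}


class ManifestError(ValueError):
    """Malformed manifest or manifest/FASTA inconsistency, with location."""


def read_manifest(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s): {', '.join(missing)}")
    dup = df["sequence_id"][df["sequence_id"].duplicated()]
    if not dup.empty:
        raise ManifestError(
            f"{path}: duplicate sequence_id entries: {sorted(set(dup))[:5]}")
    bad_pop = df.loc[~df["population"].isin(["1", "2"])]
    if not bad_pop.empty:
        row = bad_pop.iloc[0]
        raise ManifestError(
            f"{path}: unknown population code {row['population']!r} for "
            f"sequence {row['sequence_id']!r} (must be 1 or 2)")
    if "locus_type" not in df.columns:
        df["locus_type"] = ""
    if "rate_multiplier" in df.columns:
        df["rate_multiplier"] = df["rate_multiplier"].astype(float)
    else:
        df["rate_multiplier"] = [
            DEFAULT_RATE_MULTIPLIERS.get(lt, 1.0) for lt in df["locus_type"]]
    return df


def read_study(manifest_path) -> list:
    """Load and validate a study: one ``TaxonPair`` per manifest pair_id.

    FASTA paths are resolved relative to the manifest's directory.  Length
    mismatches, duplicate or missing sequence IDs and unknown population
    codes each raise a located ``ManifestError``.
    """
    manifest_path = pathlib.Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent

    # read each FASTA once
    seqs_by_file: dict = {}
    for rel in df["fasta_path"].unique():
        fp = base / rel
        if not fp.exists():
            raise ManifestError(f"{manifest_path}: FASTA file not found: {fp}")
        records = {}
        for rec in SeqIO.parse(str(fp), "fasta"):
            if rec.id in records:
                raise ManifestError(f"{fp}: duplicate FASTA record ID {rec.id!r}")
            records[rec.id] = str(rec.seq)
        seqs_by_file[rel] = records

    pairs = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        barriers = grp["barrier_id"].unique()
        if len(barriers) != 1:
            raise ManifestError(
                f"pair {pair_id!r} assigned to multiple barriers: {list(barriers)}")
        rhos = grp["rate_multiplier"].unique()
        if len(rhos) != 1:
            raise ManifestError(
                f"pair {pair_id!r} has inconsistent rate_multiplier values: {list(rhos)}")
        pop_rows: dict = {1: [], 2: []}
        ids: dict = {1: [], 2: []}
        length = None
        for _, row in grp.iterrows():
            table = seqs_by_file[row["fasta_path"]]
            sid = row["sequence_id"]
            if sid not in table:
                raise ManifestError(
                    f"{manifest_path}: sequence {sid!r} (pair {pair_id!r}) "
                    f"not found in {base / row['fasta_path']}")
            seq = encode_sequence(table[sid], where=f"{row['fasta_path']}:{sid}")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ManifestError(
                    f"pair {pair_id!r}: sequence {sid!r} has length {len(seq)}, "
                    f"expected {length}")
            pop = int(row["population"])
            pop_rows[pop].append(seq)
            ids[pop].append(sid)
        if not pop_rows[1] or not pop_rows[2]:
            raise ManifestError(f"pair {pair_id!r}: both populations need >= 1 sequence")
        pairs.append(TaxonPair(
            pair_id=str(pair_id), barrier_id=str(barriers[0]),
            pop1=np.vstack(pop_rows[1]), pop2=np.vstack(pop_rows[2]),
            rate_multiplier=float(rhos[0]),
            locus_type=str(grp["locus_type"].iloc[0]),
            seq_ids_1=ids[1], seq_ids_2=ids[2],
        ))
    return pairs


def stats_table(pairs, distances: bool = True) -> pd.DataFrame:
    """Observed statistics, one row per pair, stable column order.

    Columns: pair metadata, the per-pair summary-statistic slots, and (by
    default) the TN93 distance summary Dx/Dy/Dxy/Da.  Saturated TN93
    distances are reported as NaN rather than aborting the whole table.
    """
    rows = []
    for pair in pairs:
        row = {
            "pair_id": pair.pair_id, "barrier_id": pair.barrier_id,
            "n1": pair.n1, "n2": pair.n2, "L": pair.L,
            "rate_multiplier": pair.rate_multiplier,
        }
        row.update(dict(zip(PAIR_STAT_NAMES, pair_summary_vector(pair))))
        if distances:
            try:
                ds = distance_summary(pair)
                row.update({"Dx": ds.Dx, "Dy": ds.Dy, "Dxy": ds.Dxy, "Da": ds.Da})
            except SaturationError:
                row.update({"Dx": np.nan, "Dy": np.nan, "Dxy": np.nan, "Da": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def write_stats_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stat_layout_version={STAT_LAYOUT_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_config(path) -> dict:
    """Flat key=value configuration with explicit units in key names.

    Lines are ``key = value``; ``#`` starts a comment; values are parsed as
    int, then float, then string.  Example keys: ``tau_max_4Nref_units``,
    ``theta_max_per_site``, ``n_sims``, ``m_mean_per_barrier``.
    """
    out: dict = {}
    for lineno, raw in enumerate(pathlib.Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = val
    return out


#: config keys (with units) understood by the CLI, mapped to prior fields
CONFIG_PRIOR_KEYS = {
    "tau_max_4Nref_units": "tau_max",
    "theta_max_per_site": "theta_max",
    "theta_min_per_site": "theta_min",
    "theta_ancestral_ratio": "theta_ancestral_ratio",
    "m_mean_per_barrier": "m_mean",
    "psi_max": "psi_max",
    "n_sims": "n_sims",
    "n_accept": "n_accept",
    "kappa": "kappa",
}


def prior_kwargs_from_config(config: dict) -> dict:
    return {field: config[key] for key, field in CONFIG_PRIOR_KEYS.items()
            if key in config}
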