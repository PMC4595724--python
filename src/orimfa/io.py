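"""Readers and writers for the pipeline's on-disk formats.

FASTA via Bio.SeqIO; GFF3 parsed with gffutils (written directly — the
feature set is flat); BED / bedGraph / TSV via pandas.  Internal
coordinates are 0-based half-open everywhere; GFF3's 1-based closed
convention is converted at this boundary only.
"""

from __future__ import annotations

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Chromosome, Feature
from .mfa import MFAProfile

# ---------------------------------------------------------------- FASTA


def write_fasta(chrom: Chromosome, path):
    if chrom.sequence is None:
        raise ValueError("chromosome carries no sequence")
    rec = SeqRecord(Seq(chrom.sequence), id=chrom.name,
                    description=f"length={chrom.length} circular={chrom.circular}")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path, circular: bool = True) -> Chromosome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    rec = records[0]
    return Chromosome(name=rec.id, length=len(rec.seq), circular=circular,
                      sequence=str(rec.seq).upper())


# ---------------------------------------------------------------- GFF3


def write_gff3(features: list[Feature], chrom: Chromosome, path):
    """Write features as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom.name} 1 {chrom.length}\n")
        for f in sorted(features, key=lambda f: (f.start, f.end)):
            attrs = ";".join(
                [f"ID={f.id}"] + [f"{k}={v}" for k, v in sorted(f.attributes.items())]
            )
            fh.write(
                "\t".join(
                    [
                        chrom.name,
                        "orimfa",
                        f.type,
                        str(f.start + 1),  # to 1-based closed
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Feature]:
    """Parse a GFF3 file back into 0-based half-open features."""
    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    out = []
    for f in db.all_features():
        attrs = {k: v[0] for k, v in f.attributes.items() if k != "ID"}
        out.append(
            Feature(
                id=f.id,
                type=f.featuretype,
                start=f.start - 1,  # back to 0-based half-open
                end=f.end,
                strand=f.strand,
                attributes=attrs,
            )
        )
    out.sort(key=lambda f: (f.start, f.end))
    return out


# ---------------------------------------------------------------- probe TSV


PROBE_COLUMNS = ["probe_pos", "exp_signal", "stat_signal", "ratio"]


def write_probe_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False, columns=PROBE_COLUMNS)


def read_probe_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing probe-table columns {sorted(missing)}")
    table["status"] = "retained"
    return table


# ---------------------------------------------------------------- BED


def write_bed(reads: pd.DataFrame, path):
    reads.to_csv(path, sep="\t", index=False, header=False,
                 columns=["chrom", "start", "end"])


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED row has {len(parts)} fields, need >= 3")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if end < start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_peaks_bed6(peaks, chrom_name: str, path, span: int = 1,
                     header_comment: str | None = None):
    """Peak calls as BED6; the score column carries the peak height."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for i, p in enumerate(peaks, start=1):
            fh.write(
                "\t".join(
                    [
                        chrom_name,
                        str(p.position),
                        str(p.position + span),
                        f"peak_{i}",
                        f"{p.height:.6g}",
                        ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- bedGraph


def write_bedgraph(profile: MFAProfile, path, header_comment: str | None = None):
    """Profile as position-sorted bedGraph; each point spans to the next
    point's start (the final point runs to the chromosome end)."""
    starts = profile.positions
    ends = np.append(starts[1:], profile.chrom_length)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f'track type=bedGraph name="{profile.chrom_name} MFA"\n')
        for s, e, v in zip(starts, ends, profile.values):
            fh.write(f"{profile.chrom_name}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path, circular: bool = True, source: str = "array") -> MFAProfile:
    rows = []
    name = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph row needs 4 fields")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph row") from None
            name = parts[0]
            rows.append((start, end, value))
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    positions = np.array([r[0] for r in rows])
    values = np.array([r[2] for r in rows])
    return MFAProfile(
        positions=positions,
        values=values,
        chrom_name=name,
        chrom_length=int(rows[-1][1]),
        circular=circular,
        source=source,
    )


# ---------------------------------------------------------------- YAML / misc


def write_yaml(obj: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_predictions_gff3(predictions, chrom: Chromosome, path):
    """Origin predictions as GFF3: one origin region per prediction with its
    ORB instances as child features."""
    features = []
    for pred in predictions:
        oid = f"origin_{pred.gene_id}"
        features.append(
            Feature(oid, "replication_origin", pred.region.start, pred.region.end,
                    pred.region.gene_strand, {"anchor_gene": pred.gene_id})
        )
        for k, inst in enumerate(pred.orb.instances, start=1):
            start = pred.region.start + inst.position
            features.append(
                Feature(f"{oid}_ORB{k}", "ORB", start, start + pred.orb.length,
                        inst.strand,
                        {"Parent": oid, "consensus": pred.orb.consensus,
                         "mismatches": str(inst.mismatches)})
            )
    write_gff3(features, chrom, path)
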