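"""Readers and writers for the standard formats.

All conversions between internal 0-based half-open coordinates and the
1-based conventions of VCF/GFF3 happen here and nowhere else.  VCF is
read through cyvcf2; writing uses a small serializer because the
package constructs records from scratch.

SV dialect: insertions are written sequence-resolved when the inserted
sequence is available (REF = padding base, ALT = padding + sequence),
otherwise symbolically (<INS>/<DEL>/<INV>/<TRA>) with END and SVLEN
INFO (SVLEN negative for deletions).  A symbolic record at VCF POS p
with END e maps to the internal interval [p, e); insertions are points.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import MISSING, PAV_RECORD_COLUMNS, PavSet, PhenoTable, SnpMatrix

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_PAV = {0: "0/0", 1: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# VCF

def _vcf_header(accessions: list[str], genome: dict[str, int] | None,
                sv: bool) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=panpav"]
    for chrom, length in (genome or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    if sv:
        lines += [
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length;'
            ' negative for deletions">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end '
            '(1-based inclusive)">',
        ]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions))
    return lines


def write_snp_vcf(path: str | Path, snps: SnpMatrix,
                  genome: dict[str, int] | None = None) -> None:
    """SNP dosages as a biallelic VCF 4.2 (internal pos -> 1-based)."""
    lines = _vcf_header(snps.accessions, genome, sv=False)
    for j in range(snps.n_markers):
        gts = "\t".join(_GT[int(g)] for g in snps.dosage[:, j])
        lines.append(f"{snps.chrom[j]}\t{snps.pos[j] + 1}\t{snps.ids[j]}\t"
                     f"{snps.ref[j]}\t{snps.alt[j]}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sv_vcf(path: str | Path, pavs: PavSet,
                 genome: dict[str, int] | None = None) -> None:
    """PAV/SV records and carrier genotypes as VCF 4.2.

    Internal [start, end) maps to POS = start (the 1-based padding base
    preceding the event) and END = end (1-based inclusive last base);
    insertions carry END = POS and a positive SVLEN.
    """
    lines = _vcf_header(pavs.accessions, genome, sv=True)
    for j, (_, rec) in enumerate(pavs.records.iterrows()):
        pos = int(rec["start"])  # 1-based padding base == internal start
        svtype = rec["type"]
        length = int(rec["length"])
        if svtype == "INS":
            end = pos
            svlen = length
            if rec["sequence"]:
                ref, alt = "N", "N" + rec["sequence"]
            else:
                ref, alt = "N", "<INS>"
        else:
            end = int(rec["end"])
            svlen = -length if svtype == "DEL" else length
            ref, alt = "N", f"<{svtype}>"
        info = f"SVTYPE={svtype};SVLEN={svlen};END={end}"
        gts = "\t".join(_GT_PAV[int(g)] for g in pavs.genotypes[:, j])
        lines.append(f"{rec['chrom']}\t{pos}\t{rec['id']}\t{ref}\t{alt}\t.\t"
                     f"PASS\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def _dosages(variant, n: int) -> np.ndarray:
    out = np.empty(n, dtype=np.int8)
    for i, gt in enumerate(variant.genotypes):
        alleles = gt[:-1]
        if any(a < 0 for a in alleles):
            out[i] = MISSING
        else:
            out[i] = sum(1 for a in alleles if a > 0)
    return out


def read_vcf(path: str | Path, kind: str = "snp") -> SnpMatrix | PavSet:
    """Parse a VCF into a SnpMatrix (kind='snp') or PavSet (kind='sv').

    Multiallelic records are skipped.  VCF positions are converted to
    internal 0-based half-open coordinates; SV END/SVLEN are honored for
    symbolic ALTs, sequence-resolved indels are measured from REF/ALT.
    """
    if kind not in ("snp", "sv"):
        raise ValueError("kind must be 'snp' or 'sv'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    ids, chroms, poss, refs, alts, dosages = [], [], [], [], [], []
    records = []
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            continue
        alt = v.ALT[0]
        if kind == "snp":
            if len(v.REF) != 1 or len(alt) != 1:
                raise ValueError(
                    f"record {line_no} ({v.CHROM}:{v.POS}) is not a "
                    "biallelic SNP")
            ids.append(v.ID or f"{v.CHROM}:{v.POS}")
            chroms.append(v.CHROM)
            poss.append(v.POS - 1)
            refs.append(v.REF)
            alts.append(alt)
            dosages.append(_dosages(v, n))
            continue
        # SV parsing
        svtype = v.INFO.get("SVTYPE")
        svlen = v.INFO.get("SVLEN")
        end_info = v.INFO.get("END")
        if end_info is None and svtype not in (None, "INS"):
            end_info = v.end  # htslib folds the END INFO into the record
        symbolic = alt.startswith("<")
        if symbolic:
            svtype = svtype or alt.strip("<>")
            if svtype == "INS":
                if svlen is None:
                    raise ValueError(f"record {line_no}: symbolic INS "
                                     "without SVLEN")
                start = v.POS
                end = start
                length = abs(int(svlen))
                seq = None
            else:
                end = int(end_info) if end_info is not None else \
                    v.POS + abs(int(svlen or 0))
                start = v.POS
                length = abs(int(svlen)) if svlen is not None else end - start
                if svtype == "TRA":
                    end = start + 1
                    length = max(length, 50)
                seq = None
        else:  # sequence-resolved
            if len(alt) > len(v.REF):
                svtype = "INS"
                start = v.POS
                end = start
                length = len(alt) - len(v.REF)
                seq = alt[len(v.REF):]
            else:
                svtype = "DEL"
                start = v.POS
                end = start + len(v.REF) - len(alt)
                length = len(v.REF) - len(alt)
                seq = None
        if end < start:
            raise ValueError(f"record {line_no}: END precedes POS")
        records.append({"id": v.ID or f"sv{line_no}", "chrom": v.CHROM,
                        "start": start, "end": end, "type": svtype,
                        "length": length, "sequence": seq,
                        "left_flank": None, "right_flank": None})
        d = _dosages(v, n)
        dosages.append(np.where(d == MISSING, MISSING,
                                (d > 0).astype(np.int8)).astype(np.int8))
    if kind == "snp":
        return SnpMatrix(ids=np.array(ids), chrom=np.array(chroms),
                         pos=np.array(poss, dtype=int),
                         dosage=np.array(dosages, dtype=np.int8).T
                         if dosages else np.empty((n, 0), np.int8),
                         accessions=samples,
                         ref=np.array(refs), alt=np.array(alts))
    rec_df = pd.DataFrame(records, columns=PAV_RECORD_COLUMNS)
    geno = (np.array(dosages, dtype=np.int8).T if dosages
            else np.empty((n, 0), np.int8))
    return PavSet(records=rec_df, genotypes=geno, accessions=samples)


# ---------------------------------------------------------------------------
# intervals

def read_intervals(path: str | Path, fmt: str = "BED") -> pd.DataFrame:
    """BED (0-based half-open) or GFF3 (1-based inclusive) to internal
    0-based half-open intervals with strand and name/attributes."""
    fmt = fmt.upper()
    if fmt == "BED":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score",
                                "strand"],
                         usecols=range(6))
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    elif fmt == "GFF3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "source", "feature", "start", "end",
                                "score", "strand", "frame", "attributes"])
        df["start"] = df["start"].astype(int) - 1
        df["end"] = df["end"].astype(int)
        df["name"] = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        df = df[["chrom", "start", "end", "name", "score", "strand",
                 "feature", "attributes"]]
    else:
        raise ValueError("fmt must be BED or GFF3")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"interval start >= end at line(s) "
                         f"{[int(i) + 1 for i in bad[:5]]}")
    return df


def write_bed(path: str | Path, intervals: pd.DataFrame,
              name_col: str = "name") -> None:
    out = pd.DataFrame({
        "chrom": intervals["chrom"],
        "start": intervals["start"].astype(int),
        "end": intervals["end"].astype(int),
        "name": intervals.get(name_col, "."),
        "score": intervals.get("score", 0),
        "strand": intervals.get("strand", "."),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(path: str | Path, intervals: pd.DataFrame,
               feature: str = "gene", source: str = "panpav") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in intervals.iterrows():
            name = r.get("name", r.get("gene_id", "."))
            fh.write(f"{r['chrom']}\t{source}\t{feature}\t"
                     f"{int(r['start']) + 1}\t{int(r['end'])}\t.\t"
                     f"{r.get('strand', '.')}\t.\tID={name}\n")


# ---------------------------------------------------------------------------
# tables

def write_presence_matrix(path: str | Path, presence: pd.DataFrame) -> None:
    presence.astype(int).to_csv(path, sep="\t", index_label="family")


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ValueError("presence matrix entries must be 0/1")
    return df.astype(bool)


def write_groups(path: str | Path, groups: pd.Series) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="accession")


def read_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("accession")["group"]


def write_phenotypes(path: str | Path, pheno: PhenoTable) -> None:
    pheno.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str | Path) -> PhenoTable:
    return PhenoTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# config

def dump_config(path: str | Path, config) -> None:
    """Serialize a (dataclass) config as YAML."""
    data = config.to_dict() if hasattr(config, "to_dict") \
        else dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path: str | Path, cls):
    """Load a YAML config into dataclass ``cls``; unknown keys rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("tsd_len_range", "family_shares"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return cls(**data)
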