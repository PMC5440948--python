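"""Minimal VCF 4.2 subset reader/writer.

The interchange contract is narrow and explicit: single contig,
biallelic SNVs, QUAL carries the discovery statistic, INFO carries AF
and PROV (unknown INFO keys are preserved verbatim through a round
trip), FORMAT is GT:DS[:GL] with DS and GL written to 4 decimal places
(GL as log10).  A write -> read -> write round trip is byte-identical;
malformed records raise ``VcfParseError`` with the offending line
number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from exlwgs.calling import MISSING, CallSet

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_PARSE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING}


class VcfParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _header(sample_ids, contig, has_gl):
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig}>",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Estimated alternate allele frequency">',
        '##INFO=<ID=PROV,Number=1,Type=String,Description="Caller provenance (A, B or consensus)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">',
    ]
    if has_gl:
        lines.append(
            '##FORMAT=<ID=GL,Number=3,Type=Float,Description="Log10 genotype likelihoods">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    return lines


def write_vcf(callset: CallSet, path, gls=None, contig: str = "1") -> None:
    """Write a call set (optionally with (M, N, 3) natural-log GLs) to VCF."""
    path = Path(path)
    fmt = "GT:DS:GL" if gls is not None else "GT:DS"
    if gls is not None:
        gl10 = np.asarray(gls) / np.log(10.0)
    with open(path, "w") as fh:
        for line in _header(callset.sample_ids, contig, gls is not None):
            fh.write(line + "\n")
        for i, row in callset.sites.iterrows():
            info = f"AF={row['af']:.4f};PROV={row['provenance']}"
            extra = row.get("info_extra", "")
            if isinstance(extra, str) and extra:
                info += ";" + extra
            fields = [
                contig,
                str(int(row["position"])),
                ".",
                row["ref"],
                row["alt"],
                f"{row['stat']:.4f}",
                "PASS",
                info,
                fmt,
            ]
            for j in range(len(callset.sample_ids)):
                cell = f"{_GT_CODE[int(callset.genotypes[i, j])]}:{callset.dosages[i, j]:.4f}"
                if gls is not None:
                    cell += ":" + ",".join(f"{v:.4f}" for v in gl10[i, j])
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path):
    """Read the VCF subset written by :func:`write_vcf`.

    Returns (CallSet, gls or None); gls are natural-log, shape (M, N, 3).
    Unknown INFO keys survive verbatim in the sites column ``info_extra``.
    """
    path = Path(path)
    sample_ids = None
    positions, refs, alts, afs, stats_, provs, extras = [], [], [], [], [], [], []
    geno_rows, dos_rows, gl_rows = [], [], []
    has_gl = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VcfParseError("header has no sample columns", ln)
                sample_ids = cols[9:]
                continue
            if not line:
                continue
            if sample_ids is None:
                raise VcfParseError("record before #CHROM header", ln)
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_ids):
                raise VcfParseError(
                    f"expected {9 + len(sample_ids)} fields, found {len(fields)}", ln
                )
            try:
                positions.append(int(fields[1]))
            except ValueError:
                raise VcfParseError(f"bad POS {fields[1]!r}", ln) from None
            refs.append(fields[3])
            alts.append(fields[4])
            try:
                stats_.append(float(fields[5]))
            except ValueError:
                raise VcfParseError(f"bad QUAL {fields[5]!r}", ln) from None
            af = np.nan
            prov = ""
            extra_keys = []
            for kv in fields[7].split(";"):
                if kv.startswith("AF="):
                    af = float(kv[3:])
                elif kv.startswith("PROV="):
                    prov = kv[5:]
                elif kv:
                    extra_keys.append(kv)
            afs.append(af)
            provs.append(prov)
            extras.append(";".join(extra_keys))
            fmt_keys = fields[8].split(":")
            if has_gl is None:
                has_gl = "GL" in fmt_keys
            g_row, d_row, gl_row = [], [], []
            for s, cell in enumerate(fields[9:]):
                parts = cell.split(":")
                if len(parts) != len(fmt_keys):
                    raise VcfParseError(
                        f"sample {sample_ids[s]}: {len(parts)} subfields for "
                        f"format {fields[8]!r}",
                        ln,
                    )
                entry = dict(zip(fmt_keys, parts))
                if entry["GT"] not in _GT_PARSE:
                    raise VcfParseError(f"bad GT {entry['GT']!r}", ln)
                g_row.append(_GT_PARSE[entry["GT"]])
                d_row.append(float(entry["DS"]))
                if has_gl:
                    gl_row.append([float(v) for v in entry["GL"].split(",")])
            geno_rows.append(g_row)
            dos_rows.append(d_row)
            if has_gl:
                gl_rows.append(gl_row)
    if sample_ids is None:
        raise VcfParseError("no #CHROM header found", 0)
    sites = pd.DataFrame(
        {
            "position": positions,
            "ref": refs,
            "alt": alts,
            "af": afs,
            "stat": stats_,
            "provenance": provs,
            "info_extra": extras,
        }
    )
    callset = CallSet(
        sites=sites,
        genotypes=np.array(geno_rows, dtype=np.int8).reshape(len(sites), len(sample_ids)),
        dosages=np.array(dos_rows, dtype=float).reshape(len(sites), len(sample_ids)),
        sample_ids=sample_ids,
    )
    gls = np.array(gl_rows) * np.log(10.0) if has_gl and gl_rows else None
    return callset, gls
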