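"""Plain-text I/O: TSV matrices, SEG segment files, GMT gene sets, and
minimal VCF 4.2 with a gene/class/VAF annotation carried in INFO.

Internal coordinates are 0-based half-open; SEG files on disk follow the
common 1-based inclusive convention and are converted at this boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .subtype import SubtypeSignature


# ---------------------------------------------------------------------------
# TSV matrices and tables
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SEG files
# ---------------------------------------------------------------------------

def write_seg(segments: pd.DataFrame, path) -> None:
    """Write sample/chrom/start/end/seg_mean segments as 1-based inclusive."""
    out = segments.copy()
    out["start"] = out["start"] + 1  # 0-based half-open -> 1-based inclusive
    out.to_csv(path, sep="\t", index=False,
               header=["ID", "chrom", "loc.start", "loc.end", "seg.mean"])


def read_seg(path) -> pd.DataFrame:
    """Read a SEG-style TSV, converting to 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["sample", "chrom", "start", "end", "seg_mean"]
    df["start"] = df["start"] - 1
    return df


# ---------------------------------------------------------------------------
# GMT gene sets (plain and weighted)
# ---------------------------------------------------------------------------

def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out


def write_weighted_gmt(signatures: list[SubtypeSignature], path) -> None:
    """Signature centroids as GMT with gene:weight tokens."""
    with open(path, "w") as fh:
        for sig in signatures:
            tokens = [f"{g}:{w:.6g}" for g, w in sig.centroid.items()]
            fh.write("\t".join([sig.name, "centroid", *tokens]) + "\n")


def read_weighted_gmt(path) -> list[SubtypeSignature]:
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            genes, weights = zip(
                *(tok.rsplit(":", 1) for tok in parts[2:] if ":" in tok)
            )
            sigs.append(
                SubtypeSignature(
                    parts[0],
                    pd.Series([float(w) for w in weights], index=list(genes)),
                )
            )
    return sigs


# ---------------------------------------------------------------------------
# minimal VCF 4.2
# ---------------------------------------------------------------------------

_VCF_COLS = ["chrom", "pos", "ref", "alt", "gene", "func_class", "vaf"]


def write_vcf(calls: pd.DataFrame, path, contigs: list[str] | None = None) -> None:
    """One-sample VCF 4.2; gene, functional class and VAF travel in INFO.

    Positions are written 1-based per the VCF convention (internal positions
    are taken as 0-based).
    """
    if contigs is None:
        contigs = list(dict.fromkeys(calls["chrom"])) if len(calls) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##INFO=<ID=FCLASS,Number=1,Type=String,'
                 'Description="Functional class">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,'
                 'Description="Variant allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = calls.sort_values(["chrom", "pos"], kind="mergesort")
        for v in ordered.itertuples(index=False):
            info = f"GENE={v.gene};FCLASS={v.func_class};VAF={v.vaf}"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf(path, sample: str | None = None) -> pd.DataFrame:
    """Read a minimal annotated VCF back into a call-set DataFrame."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        rows.append(
            {
                "sample": sample or Path(path).stem,
                "chrom": rec.CHROM,
                "pos": rec.POS - 1,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "gene": rec.INFO.get("GENE"),
                "func_class": rec.INFO.get("FCLASS"),
                "vaf": rec.INFO.get("VAF"),
            }
        )
    return pd.DataFrame(rows, columns=["sample", *_VCF_COLS])


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, paths: list, meta: dict | None = None) -> Path:
    outdir = Path(outdir)
    manifest = {
        "files": {
            str(Path(p).relative_to(outdir)): file_checksum(p) for p in sorted(
                map(str, paths)
            )
        },
        **(meta or {}),
    }
    target = outdir / "manifest.json"
    with open(target, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return target
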