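"""Assembly input and pipeline output in standard formats.

Assemblies are read from FASTA; SPAdes-style ``NODE_<n>_length_<L>_cov_<c>``
headers (and an optional sidecar TSV) supply per-contig x-fold coverage,
which the collapsed-repeat heuristic needs. All internal coordinates are
0-based half-open on the forward strand; conversion to GFF3's 1-based
inclusive convention happens only at the GFF3 boundary.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

_SPADES_RE = re.compile(r"^NODE_\d+_length_\d+_cov_([0-9]+(?:\.[0-9]+)?)")
_VALID = set("ACGTN")
_IUPAC_EXTRA = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """A single assembly sequence with optional x-fold read coverage."""

    id: str
    seq: str
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"negative coverage on contig {self.id}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered collection of contigs for one species."""

    species: str
    contigs: List[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate contig ids in assembly {self.species}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def median_coverage(self) -> Optional[float]:
        """Length-weighted median coverage over contigs carrying coverage.

        The median (not the mean) is used as the baseline for the 2x
        collapsed-repeat test because collapsed repeats themselves inflate
        the upper tail of the coverage distribution.
        """
        covered = [(c.coverage, c.length) for c in self.contigs if c.coverage is not None]
        if not covered:
            return None
        covered.sort()
        half = sum(w for _, w in covered) / 2.0
        acc = 0
        for cov, w in covered:
            acc += w
            if acc >= half:
                return cov
        return covered[-1][0]


def parse_contig_header(header: str) -> Tuple[str, Optional[float]]:
    """Extract (id, coverage) from a FASTA description line (no ``>``).

    The SPAdes dialect ``NODE_<n>_length_<L>_cov_<c>`` yields coverage ``c``;
    any other header falls back to the first whitespace-delimited token with
    no coverage. Total: every header yields an id.
    """
    token = header.split()[0] if header.split() else header
    m = _SPADES_RE.match(token)
    if m:
        return token, float(m.group(1))
    return token, None


def read_coverage_sidecar(path: str) -> Dict[str, float]:
    """Read a two-column TSV (contig id, coverage) for non-SPAdes assemblies."""
    out: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, cov = line.split("\t")[:2]
            out[cid] = float(cov)
    return out


def read_assembly(
    path: str,
    species: Optional[str] = None,
    coverage_sidecar: Optional[str] = None,
    on_invalid: str = "reject",
) -> Assembly:
    """Read a FASTA assembly, uppercasing sequences and parsing coverage.

    ``on_invalid`` controls handling of non-ACGTN characters: ``'reject'``
    raises; ``'map_to_n'`` replaces IUPAC ambiguity codes with N (logged).
    Record order is preserved. An empty FASTA raises ``ValueError``.
    """
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    sidecar = read_coverage_sidecar(coverage_sidecar) if coverage_sidecar else {}
    contigs: List[Contig] = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            if on_invalid == "map_to_n" and bad <= _IUPAC_EXTRA:
                logger.warning(
                    "contig %s: mapping %d ambiguity characters to N",
                    rec.id, sum(seq.count(ch) for ch in bad),
                )
                seq = re.sub(f"[{''.join(sorted(bad))}]", "N", seq)
            else:
                raise ValueError(
                    f"contig {rec.id} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
        cid, cov = parse_contig_header(rec.description or rec.id)
        if cid in sidecar:
            cov = sidecar[cid]
        contigs.append(Contig(id=cid, seq=seq, coverage=cov))
    if not contigs:
        raise ValueError(f"empty assembly: {path}")
    if species is None:
        species = Path(path).stem
    return Assembly(species=species, contigs=contigs)


def write_assembly(assembly: Assembly, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in assembly.contigs:
            header = c.id
            fh.write(f">{header}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


@dataclass
class Gff3Feature:
    """A feature in internal coordinates (0-based half-open, forward strand)."""

    seqid: str
    type: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."
    attributes: Dict[str, str] = field(default_factory=dict)
    score: str = "."
    source: str = "matsys"


def write_gff3(features: Iterable[Gff3Feature], path: str) -> None:
    """Write features, converting [start, end) to GFF3 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str) -> List[Gff3Feature]:
    """Read a GFF3 file back into internal half-open coordinates."""
    out: List[Gff3Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, source, ftype, start, end, score, strand, _, attrs = (
                line.rstrip("\n").split("\t")
            )
            attributes = {}
            if attrs != ".":
                for kv in attrs.split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attributes[k] = v
            out.append(
                Gff3Feature(
                    seqid=seqid,
                    source=source,
                    type=ftype,
                    start=int(start) - 1,
                    end=int(end),
                    score=score,
                    strand=strand,
                    attributes=attributes,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Result export
# ---------------------------------------------------------------------------


def export_results(
    calls: Dict[str, "object"],
    loci_features: Iterable[Gff3Feature],
    summary: Optional["object"],
    outdir: str,
    tree_newick: Optional[str] = None,
) -> List[str]:
    """Write per-species calls (TSV), loci/repeats (GFF3), the transition
    summary (JSON) and, when available, the state-labelled tree (Newick).

    ``calls`` maps species name to a MatingSystemCall (duck-typed: needs
    ``category``, ``ploidy_note``, ``provisional``, ``evidence``).
    Returns the list of written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[str] = []

    calls_path = out / "calls.tsv"
    with open(calls_path, "w") as fh:
        fh.write("species\tcategory\tploidy_note\tprovisional\tevidence\n")
        for sp in sorted(calls):
            call = calls[sp]
            fh.write(
                f"{sp}\t{call.category}\t{call.ploidy_note}\t"
                f"{str(call.provisional).lower()}\t{';'.join(call.evidence)}\n"
            )
    written.append(str(calls_path))

    gff_path = out / "loci.gff3"
    feats = list(loci_features)
    loci_species = {f.attributes.get("species") for f in feats}
    for sp in calls:
        if sp not in loci_species:
            logger.warning("species %s has calls but no loci features", sp)
    write_gff3(feats, str(gff_path))
    written.append(str(gff_path))

    summary_path = out / "transitions.json"
    with open(summary_path, "w") as fh:
        if summary is None:
            json.dump(
                {
                    "n_events": 0,
                    "counts": {},
                    "to_homothallism": 0,
                    "to_heterothallism": 0,
                    "switching_origins": 0,
                    "events": [],
                },
                fh,
                indent=2,
            )
        else:
            json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")
    written.append(str(summary_path))

    if tree_newick is not None:
        tree_path = out / "states.nwk"
        with open(tree_path, "w") as fh:
            fh.write(tree_newick + "\n")
        written.append(str(tree_path))

    return written
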