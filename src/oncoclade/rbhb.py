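"""Reciprocal-best-hit homology and copy-number-by-coverage (ECNC).

Duplicate genes are detected from precomputed BLAT-style alignment tables
(PSL format): a forward search of every query isoform against a target
genome, and a reciprocal search of each candidate target locus back
against the query gene set. A target locus is accepted as a homolog of a
query gene if and only if its best reciprocal hit maps back to that gene
(reciprocal best hit). Because fragmented assemblies split one gene copy
across scaffolds — inflating naive hit counts — copy number is estimated
by coverage:

    ECNC = sum_n C_n / sum_n bool(C_n),   n = 1..l

where ``C_n`` is the number of reciprocal-best-hit loci covering query
position ``n`` and ``l`` the query length. Two fragments that tile a query
contribute the same coverage as one full-length copy, so ECNC stays near
the true copy number where raw hit counts do not.

PSL records are the standard 21-column, 0-based half-open convention.
Query coordinates are treated as residues of the (protein) query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PslError",
    "PslAlignment",
    "parse_psl",
    "write_psl",
    "score_alignment",
    "Locus",
    "merge_loci",
    "RbhHit",
    "reciprocal_best_hits",
    "EcncResult",
    "ecnc",
    "gene_copy_number",
    "GeneFilterConfig",
    "apply_exclusion_filters",
    "binarize_copy_number",
]

PSL_COLUMNS = [
    "matches", "misMatches", "repMatches", "nCount",
    "qNumInsert", "qBaseInsert", "tNumInsert", "tBaseInsert",
    "strand", "qName", "qSize", "qStart", "qEnd",
    "tName", "tSize", "tStart", "tEnd",
    "blockCount", "blockSizes", "qStarts", "tStarts",
]

class PslError(ValueError):
    """Malformed PSL input; the message carries the offending line number."""


@dataclass(frozen=True)
class PslAlignment:
    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: tuple[int, ...]
    qStarts: tuple[int, ...]
    tStarts: tuple[int, ...]

    def query_blocks(self) -> list[tuple[int, int]]:
        """Half-open covered intervals in query coordinates."""
        return [(s, s + b) for s, b in zip(self.qStarts, self.blockSizes)]

    def query_coverage_length(self) -> int:
        return sum(b for b in self.blockSizes)

    def validate(self) -> None:
        if self.blockCount != len(self.blockSizes) or self.blockCount != len(
            self.qStarts
        ) or self.blockCount != len(self.tStarts):
            raise PslError("blockCount inconsistent with block lists")
        for v in (self.matches, self.misMatches, self.repMatches, self.nCount,
                  self.qNumInsert, self.tNumInsert):
            if v < 0:
                raise PslError("negative count field")
        prev_end = -1
        for qs, bs in zip(self.qStarts, self.blockSizes):
            if bs <= 0:
                raise PslError("non-positive block size")
            if qs < prev_end:
                raise PslError("query blocks overlap or are unsorted")
            prev_end = qs + bs
            if qs + bs > self.qSize:
                raise PslError("query block exceeds qSize")
        for ts, bs in zip(self.tStarts, self.blockSizes):
            if ts + bs > self.tSize:
                raise PslError("target block exceeds tSize")
        if self.qStarts and self.qStarts[0] != self.qStart:
            raise PslError("first query block start disagrees with qStart")
        if self.qStarts and self.qStarts[-1] + self.blockSizes[-1] != self.qEnd:
            raise PslError("last query block end disagrees with qEnd")
        if self.tStarts and self.tStarts[0] != self.tStart:
            raise PslError("first target block start disagrees with tStart")
        if self.tStarts and self.tStarts[-1] + self.blockSizes[-1] != self.tEnd:
            raise PslError("last target block end disagrees with tEnd")


def _parse_int_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")


def parse_psl(source) -> list[PslAlignment]:
    """Parse PSL from a path or an iterable of lines (header optional).

    The optional 5-line ``psLayout`` header is skipped. Malformed lines
    raise :class:`PslError` naming the line number.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    start = 0
    if lines and lines[0].startswith("psLayout"):
        for i, line in enumerate(lines):
            if line.startswith("---"):
                start = i + 1
                break
        else:
            raise PslError("psLayout header never terminated by a dashed line")

    records: list[PslAlignment] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 21:
            raise PslError(f"line {lineno}: expected 21 columns, got {len(fields)}")
        try:
            rec = PslAlignment(
                matches=int(fields[0]), misMatches=int(fields[1]),
                repMatches=int(fields[2]), nCount=int(fields[3]),
                qNumInsert=int(fields[4]), qBaseInsert=int(fields[5]),
                tNumInsert=int(fields[6]), tBaseInsert=int(fields[7]),
                strand=fields[8], qName=fields[9], qSize=int(fields[10]),
                qStart=int(fields[11]), qEnd=int(fields[12]), tName=fields[13],
                tSize=int(fields[14]), tStart=int(fields[15]), tEnd=int(fields[16]),
                blockCount=int(fields[17]),
                blockSizes=_parse_int_list(fields[18]),
                qStarts=_parse_int_list(fields[19]),
                tStarts=_parse_int_list(fields[20]),
            )
            rec.validate()
        except PslError as exc:
            raise PslError(f"line {lineno}: {exc}") from None
        except ValueError as exc:
            raise PslError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def write_psl(records, path) -> None:
    """Write 21-column headerless PSL."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.matches, r.misMatches, r.repMatches, r.nCount,
                        r.qNumInsert, r.qBaseInsert, r.tNumInsert, r.tBaseInsert,
                        r.strand, r.qName, r.qSize, r.qStart, r.qEnd,
                        r.tName, r.tSize, r.tStart, r.tEnd, r.blockCount,
                        ",".join(map(str, r.blockSizes)) + ",",
                        ",".join(map(str, r.qStarts)) + ",",
                        ",".join(map(str, r.tStarts)) + ",",
                    )
                )
                + "\n"
            )


def score_alignment(a: PslAlignment) -> int:
    """Deterministic ranking score: matches + repMatches - misMatches - gaps."""
    return a.matches + a.repMatches - a.misMatches - a.qNumInsert - a.tNumInsert


# ----------------------------------------------------------------------- loci
@dataclass
class Locus:
    """A merged target-genome region hit by one query isoform."""

    locus_id: str
    tName: str
    start: int
    end: int
    alignments: list[PslAlignment] = field(default_factory=list)

    @property
    def score(self) -> int:
        return max(score_alignment(a) for a in self.alignments)

    def query_blocks(self) -> list[tuple[int, int]]:
        return [blk for a in self.alignments for blk in a.query_blocks()]

    def query_coverage_length(self) -> int:
        spans = sorted(self.query_blocks())
        total, cur_s, cur_e = 0, None, None
        for s, e in spans:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total


def merge_loci(alignments: list[PslAlignment], max_gap: int = 10_000) -> list[Locus]:
    """Merge one isoform's hits on the same target within ``max_gap`` bases.

    BLAT reports exon-level hits; without merging, one gene copy would be
    counted several times. Hits on the same scaffold whose target spans
    overlap or lie within ``max_gap`` form one locus.
    """
    by_target: dict[str, list[PslAlignment]] = {}
    for a in alignments:
        by_target.setdefault(a.tName, []).append(a)
    loci: list[Locus] = []
    for tname, hits in sorted(by_target.items()):
        hits = sorted(hits, key=lambda a: (a.tStart, a.tEnd))
        cur: list[PslAlignment] = []
        cur_end = None
        for a in hits:
            if cur and a.tStart > cur_end + max_gap:
                loci.append(_make_locus(tname, cur))
                cur = []
            cur.append(a)
            cur_end = a.tEnd if cur_end is None or a.tEnd > cur_end else cur_end
        if cur:
            loci.append(_make_locus(tname, cur))
    return loci


def _make_locus(tname: str, hits: list[PslAlignment]) -> Locus:
    start = min(a.tStart for a in hits)
    end = max(a.tEnd for a in hits)
    return Locus(f"{tname}:{start}-{end}", tname, start, end, hits)


# ------------------------------------------------------------------------ RBH
@dataclass
class RbhHit:
    """A target locus whose best reciprocal hit maps back to its query gene."""

    query_gene: str
    query_isoform: str
    locus: Locus
    forward_score: int
    reciprocal_gene: str


def reciprocal_best_hits(
    forward: list[PslAlignment],
    reciprocal: list[PslAlignment],
    isoform_to_gene: dict[str, str],
    max_gap: int = 10_000,
) -> tuple[list[RbhHit], dict]:
    """Retain forward loci whose best reciprocal hit is the original gene.

    ``reciprocal`` records must carry locus ids (``tName:start-end`` as
    emitted by :func:`merge_loci`) as their ``qName``. Ties in the
    reciprocal ranking are broken by (score, query coverage length,
    lexicographic target name) for determinism. Loci absent from the
    reciprocal table are dropped and counted in the diagnostics.
    """
    recip_by_locus: dict[str, list[PslAlignment]] = {}
    for a in reciprocal:
        recip_by_locus.setdefault(a.qName, []).append(a)

    forward_by_isoform: dict[str, list[PslAlignment]] = {}
    for a in forward:
        forward_by_isoform.setdefault(a.qName, []).append(a)

    hits: list[RbhHit] = []
    diagnostics = {"n_loci": 0, "missing_reciprocal": 0, "non_reciprocal": 0}
    for isoform, aligns in sorted(forward_by_isoform.items()):
        if isoform not in isoform_to_gene:
            raise KeyError(f"isoform {isoform!r} missing from isoform->gene map")
        gene = isoform_to_gene[isoform]
        for locus in merge_loci(aligns, max_gap=max_gap):
            diagnostics["n_loci"] += 1
            back = recip_by_locus.get(locus.locus_id)
            if not back:
                diagnostics["missing_reciprocal"] += 1
                continue
            best = min(
                back,
                key=lambda a: (
                    -score_alignment(a),
                    -a.query_coverage_length(),
                    a.tName,  # lexicographically smallest target wins on full tie
                ),
            )
            best_gene = isoform_to_gene.get(best.tName, best.tName)
            if best_gene == gene:
                hits.append(RbhHit(gene, isoform, locus, locus.score, best_gene))
            else:
                diagnostics["non_reciprocal"] += 1
    return hits, diagnostics


# ----------------------------------------------------------------------- ECNC
@dataclass
class EcncResult:
    """The coverage-corrected copy-number statistic for one query isoform."""

    query_isoform: str
    length: int
    ecnc: float  # nan when undefined (no covered position)
    covered_fraction: float
    n_hits: int

    @property
    def defined(self) -> bool:
        return self.n_hits > 0 and self.covered_fraction > 0


def ecnc(query_length: int, hits: list[RbhHit], query_isoform: str = "") -> EcncResult:
    """ECNC = sum_n C_n / sum_n bool(C_n) over query positions n = 1..l.

    Each reciprocal-best-hit locus contributes 1 to ``C_n`` at every query
    position it covers (union of its alignment blocks — a locus is one
    putative copy, so internal block overlap is not double-counted).
    """
    if query_length <= 0:
        raise ValueError("query length must be positive")
    coverage = np.zeros(query_length, dtype=np.int64)
    for h in hits:
        mask = np.zeros(query_length, dtype=bool)
        for s, e in h.locus.query_blocks():
            mask[s:e] = True
        coverage += mask
    covered = coverage > 0
    n_cov = int(covered.sum())
    value = float(coverage.sum() / n_cov) if n_cov else float("nan")
    return EcncResult(
        query_isoform=query_isoform,
        length=query_length,
        ecnc=value,
        covered_fraction=n_cov / query_length,
        n_hits=len(hits),
    )


def gene_copy_number(
    isoform_results: list[tuple[str, EcncResult, int]],
    isoform_to_gene: dict[str, str],
    how: str = "max",
) -> tuple[pd.DataFrame, dict]:
    """Aggregate isoform-level (ECNC, n_loci) to genes.

    ``isoform_results`` holds (isoform, EcncResult, n_loci) triples. The
    default aggregation is the max over isoforms (longest-signal rule);
    ``how="mean"`` averages instead. Isoforms with undefined ECNC are
    skipped; genes left with no scored isoform are absent from the output
    and listed in the diagnostics.
    """
    if how not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {how!r}")
    per_gene: dict[str, list[tuple[float, int]]] = {}
    unscored: set[str] = set()
    for isoform, res, n_loci in isoform_results:
        if isoform not in isoform_to_gene:
            raise KeyError(f"isoform {isoform!r} missing from isoform->gene map")
        gene = isoform_to_gene[isoform]
        if not res.defined:
            unscored.add(gene)
            continue
        per_gene.setdefault(gene, []).append((res.ecnc, n_loci))
    rows = []
    for gene, vals in sorted(per_gene.items()):
        ecncs = [v[0] for v in vals]
        loci = [v[1] for v in vals]
        if how == "max":
            rows.append((gene, max(ecncs), max(loci)))
        else:
            rows.append((gene, float(np.mean(ecncs)), int(round(np.mean(loci)))))
    df = pd.DataFrame(rows, columns=["gene", "ecnc", "n_loci"])
    diagnostics = {"genes_without_scored_isoforms": sorted(unscored - set(per_gene))}
    return df, diagnostics


# -------------------------------------------------------------------- filters
@dataclass
class GeneFilterConfig:
    """Regex exclusion lists for query genes with unreliable homology.

    Categories mirror common practice for human proteome query sets:
    uncharacterized ORFs, LOC placeholders, HLA, replication-dependent
    histones, odorant receptors, ribosomal proteins, zinc-finger
    transcription factors, viral/repeat-associated proteins, and names
    flagged Uncharacterized/Putative/Fragment. Patterns are explicit data
    so they can be serialised with each run.
    """

    patterns: dict[str, list[str]] = field(
        default_factory=lambda: {
            "uncharacterized_orf": [r"^C[0-9XY]+orf\d+$"],
            "loc": [r"^LOC\d+$"],
            "hla": [r"^HLA-"],
            "histone": [r"^HIST\d", r"^H[1-4]-\d+$", r"^H2[AB]C\d+$"],
            "odorant_receptor": [r"^OR\d+[A-Z]\d*"],
            "ribosomal": [r"^M?RP[LS]\d+"],
            "zinc_finger": [r"^Z(NF|FP)\d+"],
            "viral_repeat": [r"^(ERV|HERV|LINE|L1RE)\w*"],
            "uncertain_name": [r"(?i)uncharacterized|putative|fragment"],
        }
    )


def apply_exclusion_filters(
    genes, cfg: GeneFilterConfig | None = None
) -> tuple[list[str], dict[str, int]]:
    """Drop genes matching any exclusion pattern; count removals per category.

    Set semantics: the result is order-independent (sorted) and each gene
    is counted once per category at most, first matching category wins for
    the removal tally.
    """
    cfg = cfg or GeneFilterConfig()
    compiled = {
        cat: [re.compile(p) for p in pats] for cat, pats in cfg.patterns.items()
    }
    counts = {cat: 0 for cat in cfg.patterns}
    retained = []
    for gene in sorted(set(genes)):
        hit = None
        for cat, pats in compiled.items():
            if any(p.search(gene) for p in pats):
                hit = cat
                break
        if hit is None:
            retained.append(gene)
        else:
            counts[hit] += 1
    return retained, counts


# ----------------------------------------------------------------- binarize
def binarize_copy_number(
    gene_table: pd.DataFrame, n_loci_min: int = 2, ecnc_min: float = 1.5
) -> pd.DataFrame:
    """Call duplicated (1) vs single copy (0) per gene.

    State 1 requires both ``n_loci >= n_loci_min`` and ``ecnc >= ecnc_min``:
    a fragmented single copy shows extra loci but ECNC near 1 and stays 0.
    Thresholds are attached to the result for serialisation.
    """
    out = gene_table.copy()
    out["state"] = (
        (out["n_loci"] >= n_loci_min) & (out["ecnc"] >= ecnc_min)
    ).astype(int)
    out.attrs["n_loci_min"] = n_loci_min
    out.attrs["ecnc_min"] = ecnc_min
    return out
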