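"""Polarized SNP matrix: segregating sites x sampled alleles.

The on-disk contract is a TSV dialect: an initial ``#paralog`` comment line
mapping each allele column to its paralog of origin (P1/P2/P3), a header
row ``pos  anc  <allele ids...>``, then one row per site with a 1-based
position, the ancestral state symbol, and one state call per allele.
Calls are ``0``/``1`` (ancestral/derived) or letter states (equal to the
ancestral letter -> ancestral, anything else -> derived) with ``-`` for a
gap.  Positions are 1-based and strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

GAP = -1

_PARALOG_SYNONYMS = {"P1": "P1", "P2": "P2", "P3": "P3",
                     "copy1": "P1", "copy2": "P2", "copy3": "P3"}


class MatrixParseError(ValueError):
    """Malformed SNP-matrix file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class PolarizedSNPMatrix:
    """Derived/ancestral calls at segregating sites for labeled alleles."""

    positions: np.ndarray          # int64, 1-based, strictly increasing
    anc: np.ndarray                # ancestral state symbol per site
    data: np.ndarray               # int8 (n_sites, n_alleles): 0/1/GAP
    allele_ids: list
    paralogs: list                 # P1/P2/P3 per allele
    total_sites: int | None = None  # alignment length the sites came from

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.positions):
            raise ValueError("data must be (n_sites, n_alleles)")
        if len(self.allele_ids) != self.data.shape[1]:
            raise ValueError("allele_ids length mismatch")
        if len(self.paralogs) != self.data.shape[1]:
            raise ValueError("paralogs length mismatch")
        bad = set(self.paralogs) - set(_PARALOG_SYNONYMS)
        if bad:
            raise ValueError(f"unknown paralog label(s): {sorted(bad)}")
        self.paralogs = [_PARALOG_SYNONYMS[p] for p in self.paralogs]
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.data.shape[1]

    def columns_of(self, paralog: str) -> np.ndarray:
        p = _PARALOG_SYNONYMS.get(paralog)
        if p is None:
            raise ValueError(f"unknown paralog label: {paralog!r}")
        return np.flatnonzero(np.asarray(self.paralogs) == np.asarray(p))

    def submatrix(self, paralog: str) -> "PolarizedSNPMatrix":
        cols = self.columns_of(paralog)
        return PolarizedSNPMatrix(
            positions=self.positions.copy(), anc=self.anc.copy(),
            data=self.data[:, cols].copy(),
            allele_ids=[self.allele_ids[c] for c in cols],
            paralogs=[self.paralogs[c] for c in cols],
            total_sites=self.total_sites)

    # -- IO -----------------------------------------------------------------

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            pairs = "\t".join(f"{a}={p}" for a, p in
                              zip(self.allele_ids, self.paralogs))
            fh.write(f"#paralog\t{pairs}\n")
            if self.total_sites is not None:
                fh.write(f"#total_sites\t{self.total_sites}\n")
            fh.write("pos\tanc\t" + "\t".join(map(str, self.allele_ids)) + "\n")
            sym = {0: "0", 1: "1", GAP: "-"}
            for i in range(self.n_sites):
                calls = "\t".join(sym[int(v)] for v in self.data[i])
                fh.write(f"{self.positions[i]}\t{self.anc[i]}\t{calls}\n")

    def to_fasta(self, path) -> None:
        """Write sampled alleles as FASTA over segregating sites
        (0 -> A, 1 -> T, gap -> '-')."""
        lut = {0: "A", 1: "T", GAP: "-"}
        with open(path, "w") as fh:
            for j, (aid, par) in enumerate(zip(self.allele_ids, self.paralogs)):
                seq = "".join(lut[int(v)] for v in self.data[:, j])
                fh.write(f">{aid}|{par}\n{seq}\n")


def read_snp_matrix(path) -> PolarizedSNPMatrix:
    """Parse the TSV dialect written by ``PolarizedSNPMatrix.write_tsv``."""
    paralog_map: dict[str, str] = {}
    total_sites = None
    header: list[str] | None = None
    positions, ancs, rows = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#paralog"):
                for tok in line.split("\t")[1:]:
                    if "=" not in tok:
                        raise MatrixParseError(
                            f"malformed paralog mapping {tok!r}", lineno)
                    aid, par = tok.split("=", 1)
                    if par not in _PARALOG_SYNONYMS:
                        raise MatrixParseError(
                            f"unknown paralog label {par!r}", lineno)
                    paralog_map[aid] = par
                continue
            if line.startswith("#total_sites"):
                total_sites = int(line.split("\t")[1])
                continue
            if line.startswith("#"):
                continue
            toks = line.split("\t")
            if header is None:
                if toks[:2] != ["pos", "anc"]:
                    raise MatrixParseError(
                        "header must start with 'pos\\tanc'", lineno)
                header = toks[2:]
                missing = [a for a in header if a not in paralog_map]
                if missing:
                    raise MatrixParseError(
                        f"missing paralog mapping for allele(s) {missing}",
                        lineno)
                continue
            if len(toks) != len(header) + 2:
                raise MatrixParseError(
                    f"expected {len(header) + 2} fields, got {len(toks)}",
                    lineno)
            try:
                pos = int(toks[0])
            except ValueError:
                raise MatrixParseError(f"bad position {toks[0]!r}", lineno)
            anc = toks[1]
            row = np.empty(len(header), dtype=np.int8)
            for j, call in enumerate(toks[2:]):
                if call == "-":
                    row[j] = GAP
                elif call in ("0", anc):
                    row[j] = 0
                elif call == "1" or (call.isalpha() and len(call) == 1):
                    row[j] = 1
                else:
                    raise MatrixParseError(
                        f"unknown state symbol {call!r}", lineno)
            if positions and pos <= positions[-1]:
                raise MatrixParseError(
                    f"duplicate or non-increasing position {pos}", lineno)
            positions.append(pos)
            ancs.append(anc)
            rows.append(row)
    if header is None:
        raise MatrixParseError("no header row found")
    if not paralog_map:
        raise MatrixParseError("missing #paralog mapping line")
    data = (np.vstack(rows) if rows
            else np.empty((0, len(header)), dtype=np.int8))
    return PolarizedSNPMatrix(
        positions=np.asarray(positions, dtype=np.int64),
        anc=np.asarray(ancs), data=data, allele_ids=list(header),
        paralogs=[paralog_map[a] for a in header], total_sites=total_sites)


def read_fasta_alignment(path, ancestral_id: str,
                         paralog_map: dict | None = None) -> PolarizedSNPMatrix:
    """Extract segregating columns from an equal-length FASTA alignment and
    polarize them against the record named ``ancestral_id``.

    Paralog labels come from ``paralog_map`` (record id -> P1/P2/P3) or, by
    default, from a trailing ``_P1``/``|P1`` style token in each record id.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MatrixParseError("empty FASTA file")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise MatrixParseError(f"ragged alignment: lengths {sorted(lengths)}")
    by_id = {r.id: r for r in records}
    if ancestral_id not in by_id:
        raise MatrixParseError(f"ancestral record {ancestral_id!r} not found")
    anc_seq = np.frombuffer(str(by_id[ancestral_id].seq).upper().encode(),
                            dtype="S1")
    samples = [r for r in records if r.id != ancestral_id]

    def _label(rid: str) -> str:
        if paralog_map is not None:
            if rid not in paralog_map:
                raise MatrixParseError(f"no paralog label for record {rid!r}")
            return paralog_map[rid]
        for sep in ("|", "_"):
            tail = rid.rsplit(sep, 1)[-1]
            if tail in _PARALOG_SYNONYMS:
                return tail
        raise MatrixParseError(
            f"cannot infer paralog of record {rid!r}; pass paralog_map")

    labels = [_label(r.id) for r in samples]
    mat = np.vstack([np.frombuffer(str(r.seq).upper().encode(), dtype="S1")
                     for r in samples])
    gap = (mat == b"-") | (mat == b"N")
    derived = (mat != anc_seq) & ~gap
    nongap_counts = (~gap).sum(axis=0)
    dcount = derived.sum(axis=0)
    seg = (dcount > 0) & (dcount < nongap_counts) & (anc_seq != b"-")
    data = np.where(gap, GAP, derived.astype(np.int8))[:, seg].T
    return PolarizedSNPMatrix(
        positions=np.flatnonzero(seg) + 1,
        anc=anc_seq[seg].astype("U1"),
        data=data, allele_ids=[r.id for r in samples], paralogs=labels,
        total_sites=len(anc_seq))
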