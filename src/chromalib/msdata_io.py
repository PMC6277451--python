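"""Readers and writers for mzML runs, MSP spectrum libraries, SQLite
spectrum/chromatogram libraries, and FASTA protein digests.

The mzML support targets the subset of the HUPO PSI standard needed for
centroided DIA data: MS level, scan start time, isolation window metadata and
64/32-bit (optionally zlib-compressed) peak arrays. Profile-mode spectra are
rejected.
"""

from __future__ import annotations

import base64
import logging
import re
import sqlite3
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path

import numpy as np

from . import masses
from .masses import FragmentAnnotation
from .models import DIARun, Library, LibraryEntry, Spectrum

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _decode_binary(elem) -> tuple[np.ndarray, bool]:
    accs = {
        cv.get("accession")
        for cv in elem.iter()
        if cv.tag.endswith("cvParam")
    }
    text_el = next((c for c in elem.iter() if c.tag.endswith("}binary")), None)
    raw = base64.b64decode(text_el.text or "")
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = np.float32 if _ACC_32BIT in accs else np.float64
    arr = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    return arr, _ACC_MZ_ARRAY in accs


def read_mzml(path: str | Path, demultiplex: bool = False) -> DIARun:
    """Read a centroided mzML file into a :class:`DIARun`.

    The isolation-window scheme is inferred from the observed
    (center, width) pairs on MS2 scans. With ``demultiplex=True``, MS2
    spectra of a 50%-overlapped scheme are replaced by half-width
    pseudo-spectra (see :mod:`chromalib.demultiplex`).
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    for _, elem in ET.iterparse(str(path)):
        if not elem.tag.endswith("}spectrum") and elem.tag != "spectrum":
            continue
        scan_id = elem.get("id", "")
        ms_level = None
        rt = None
        center = None
        lower = upper = None
        profile = False
        for cv in elem.iter():
            if not cv.tag.endswith("cvParam"):
                continue
            acc = cv.get("accession")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(cv.get("value"))
            elif acc == _ACC_PROFILE:
                profile = True
            elif acc == _ACC_SCAN_START:
                rt = float(cv.get("value"))
                if cv.get("unitName", "minute").startswith("second"):
                    rt /= 60.0
            elif acc == _ACC_ISO_TARGET:
                center = float(cv.get("value"))
            elif acc == _ACC_ISO_LOWER:
                lower = float(cv.get("value"))
            elif acc == _ACC_ISO_UPPER:
                upper = float(cv.get("value"))
        if profile:
            raise ValueError(f"profile-mode spectrum not supported (scan {scan_id})")
        mzs = np.array([])
        intens = np.array([])
        for bda in elem.iter():
            if bda.tag.endswith("}binaryDataArray") or bda.tag == "binaryDataArray":
                arr, is_mz = _decode_binary(bda)
                if is_mz:
                    mzs = arr
                else:
                    intens = arr
        width = None
        if ms_level == 2:
            if center is None or lower is None or upper is None:
                raise ValueError(
                    f"MS2 scan {scan_id!r} lacks isolation window metadata"
                )
            width = lower + upper
        order = np.argsort(mzs, kind="stable")
        spectra.append(
            Spectrum(
                scan_id=scan_id,
                ms_level=ms_level or 1,
                rt=rt or 0.0,
                mzs=mzs[order],
                intensities=intens[order],
                isolation_center=center if ms_level == 2 else None,
                isolation_width=width,
            )
        )
        elem.clear()
    spectra.sort(key=lambda s: s.rt)
    scheme = sorted(
        {
            (round(s.isolation_center - s.isolation_width / 2, 6),
             round(s.isolation_center + s.isolation_width / 2, 6))
            for s in spectra
            if s.ms_level == 2
        }
    )
    run = DIARun(run_id=path.stem, spectra=spectra, window_scheme=scheme)
    if demultiplex:
        from .demultiplex import demultiplex_run

        run = demultiplex_run(run)
    return run


def write_mzml(run: DIARun, path: str | Path) -> None:
    """Write a minimal, standard-conforming centroided mzML file."""
    path = Path(path)

    def b64(arr: np.ndarray) -> str:
        return base64.b64encode(
            struct.pack(f"<{arr.size}d", *arr.astype(np.float64))
        ).decode()

    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        f'  <run id="{run.run_id}">',
        f'    <spectrumList count="{len(run.spectra)}">',
    ]
    for i, s in enumerate(run.spectra):
        lines.append(
            f'      <spectrum index="{i}" id="{s.scan_id}" '
            f'defaultArrayLength="{s.mzs.size}">'
        )
        lines.append(
            f'        <cvParam cvRef="MS" accession="MS:1000511" '
            f'name="ms level" value="{s.ms_level}"/>'
        )
        lines.append(
            '        <cvParam cvRef="MS" accession="MS:1000127" '
            'name="centroid spectrum" value=""/>'
        )
        lines.append("        <scanList count=\"1\"><scan>")
        lines.append(
            f'          <cvParam cvRef="MS" accession="MS:1000016" '
            f'name="scan start time" value="{s.rt!r}" unitName="minute"/>'
        )
        lines.append("        </scan></scanList>")
        if s.ms_level == 2:
            h = s.isolation_width / 2.0
            lines.append(
                "        <precursorList count=\"1\"><precursor>"
                "<isolationWindow>"
                f'<cvParam cvRef="MS" accession="MS:1000827" '
                f'name="isolation window target m/z" value="{s.isolation_center!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000828" '
                f'name="isolation window lower offset" value="{h!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000829" '
                f'name="isolation window upper offset" value="{h!r}"/>'
                "</isolationWindow></precursor></precursorList>"
            )
        lines.append('        <binaryDataArrayList count="2">')
        for arr, acc, name in (
            (s.mzs, "MS:1000514", "m/z array"),
            (s.intensities, "MS:1000515", "intensity array"),
        ):
            lines.append("          <binaryDataArray>")
            lines.append(
                '            <cvParam cvRef="MS" accession="MS:1000523" '
                'name="64-bit float" value=""/>'
            )
            lines.append(
                '            <cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression" value=""/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{acc}" '
                f'name="{name}" value=""/>'
            )
            lines.append(f"            <binary>{b64(arr)}</binary>")
            lines.append("          </binaryDataArray>")
        lines.append("        </binaryDataArrayList>")
        lines.append("      </spectrum>")
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# MSP spectrum libraries
# ---------------------------------------------------------------------------

_MSP_ANNOT_RE = re.compile(r"^([by])(\d+)(?:\^(\d+))?", re.IGNORECASE)


def parse_msp_annotation(text: str) -> FragmentAnnotation | None:
    """Parse annotations like ``y5``, ``b3^2``; returns None if unparseable."""
    m = _MSP_ANNOT_RE.match(text.strip().strip('"'))
    if not m:
        return None
    return FragmentAnnotation(m.group(1).upper(), int(m.group(2)), int(m.group(3) or 1))


def read_msp(path: str | Path) -> Library:
    """Read a NIST MSP text library.

    Unparseable blocks are skipped with a logged warning; unannotated peaks
    are retained with a ``None`` annotation; fragment correlations default
    to 1.0.
    """
    lib = Library()
    skipped = 0
    block: list[str] = []

    def flush(block: list[str]) -> None:
        nonlocal skipped
        if not block:
            return
        try:
            entry = _parse_msp_block(block)
        except Exception as exc:  # noqa: BLE001 - skip-and-count contract
            skipped += 1
            logger.warning("skipping unparseable MSP block: %s", exc)
            return
        lib.add(entry)

    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip()
        if line.lower().startswith("name:") and block:
            flush(block)
            block = []
        if line:
            block.append(line)
    flush(block)
    if skipped:
        logger.warning("skipped %d unparseable MSP blocks", skipped)
    if not len(lib):
        logger.warning("MSP file %s produced an empty library", path)
    return lib


def _parse_msp_block(block: list[str]) -> LibraryEntry:
    header: dict[str, str] = {}
    peaks: list[tuple[float, float, FragmentAnnotation | None]] = []
    in_peaks = False
    for line in block:
        if in_peaks:
            parts = line.split(None, 2)
            mz, inten = float(parts[0]), float(parts[1])
            ann = parse_msp_annotation(parts[2]) if len(parts) > 2 else None
            peaks.append((mz, inten, ann))
            continue
        if ":" in line:
            key, val = line.split(":", 1)
            header[key.strip().lower()] = val.strip()
            if key.strip().lower() == "num peaks":
                in_peaks = True
    name = header["name"]
    if "/" in name:
        seq, charge_s = name.rsplit("/", 1)
        charge = int(charge_s)
    else:
        seq, charge = name, 2
    comment = header.get("comment", "")
    rt = 0.0
    m = re.search(r"RTINSECONDS=([\d.]+)", comment)
    if m:
        rt = float(m.group(1)) / 60.0
    else:
        m = re.search(r"\bRT=([\d.]+)", comment)
        if m:
            rt = float(m.group(1))
    peaks.sort(key=lambda p: p[0])
    mzs = np.array([p[0] for p in peaks])
    intens = np.array([p[1] for p in peaks])
    anns = [p[2] for p in peaks]
    pmz = header.get("precursormz")
    precursor = float(pmz) if pmz else masses.precursor_mz(seq, charge)
    return LibraryEntry(
        peptide_modseq=seq,
        charge=charge,
        precursor_mz=precursor,
        library_rt=rt,
        fragment_mzs=mzs,
        fragment_intensities=intens,
        fragment_annotations=anns,
        source="spectrum_library",
    )


# ---------------------------------------------------------------------------
# SQLite libraries
# ---------------------------------------------------------------------------

def write_sqlite_library(lib: Library, path: str | Path) -> None:
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(str(path))
    try:
        con.executescript(
            """
            CREATE TABLE meta(key TEXT PRIMARY KEY, value TEXT);
            CREATE TABLE entries(
                modseq TEXT, charge INT, precursor_mz REAL, rt_sec REAL,
                is_decoy INT, source TEXT, degenerate_decoy INT,
                mz BLOB, intensity BLOB, correlation BLOB, annotation BLOB
            );
            CREATE TABLE peptide_protein(modseq TEXT, accession TEXT);
            """
        )
        con.execute("INSERT INTO meta VALUES('schema_version', ?)", (SCHEMA_VERSION,))
        for e in lib:
            ann_blob = b""
            if e.fragment_annotations is not None:
                ann_blob = ";".join(
                    "" if a is None else f"{a.ion_type},{a.index},{a.charge}"
                    for a in e.fragment_annotations
                ).encode()
            con.execute(
                "INSERT INTO entries VALUES(?,?,?,?,?,?,?,?,?,?,?)",
                (
                    e.peptide_modseq,
                    e.charge,
                    e.precursor_mz,
                    e.library_rt * 60.0,
                    int(e.is_decoy),
                    e.source,
                    int(e.degenerate_decoy),
                    e.fragment_mzs.astype("<f8").tobytes(),
                    e.fragment_intensities.astype("<f8").tobytes(),
                    e.fragment_correlations.astype("<f8").tobytes(),
                    ann_blob,
                ),
            )
        con.executemany(
            "INSERT INTO peptide_protein VALUES(?,?)",
            [(pep, acc) for pep, accs in lib.protein_map.items() for acc in sorted(accs)],
        )
        con.commit()
    finally:
        con.close()


def read_sqlite_library(path: str | Path) -> Library:
    con = sqlite3.connect(str(path))
    try:
        try:
            row = con.execute(
                "SELECT value FROM meta WHERE key='schema_version'"
            ).fetchone()
        except sqlite3.DatabaseError as exc:
            raise ValueError(f"{path} is not a chromalib SQLite library") from exc
        if row is None or row[0] != SCHEMA_VERSION:
            raise ValueError(
                f"library schema version mismatch: expected {SCHEMA_VERSION}, "
                f"found {row[0] if row else 'none'}"
            )
        lib = Library()
        for (
            modseq, charge, pmz, rt_sec, is_decoy, source, degenerate,
            mz_b, int_b, corr_b, ann_b,
        ) in con.execute("SELECT * FROM entries"):
            anns = None
            if ann_b:
                anns = []
                for part in ann_b.decode().split(";"):
                    if not part:
                        anns.append(None)
                    else:
                        t, i, z = part.split(",")
                        anns.append(FragmentAnnotation(t, int(i), int(z)))
            lib.add(
                LibraryEntry(
                    peptide_modseq=modseq,
                    charge=charge,
                    precursor_mz=pmz,
                    library_rt=rt_sec / 60.0,
                    fragment_mzs=np.frombuffer(mz_b, dtype="<f8"),
                    fragment_intensities=np.frombuffer(int_b, dtype="<f8"),
                    fragment_correlations=np.frombuffer(corr_b, dtype="<f8"),
                    fragment_annotations=anns,
                    is_decoy=bool(is_decoy),
                    source=source,
                    degenerate_decoy=bool(degenerate),
                )
            )
        for pep, acc in con.execute("SELECT modseq, accession FROM peptide_protein"):
            lib.protein_map.setdefault(pep, set()).add(acc)
        return lib
    finally:
        con.close()


# ---------------------------------------------------------------------------
# FASTA digestion
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Accession -> sequence; on duplicate accessions the last wins."""
    seqs: dict[str, str] = {}
    acc = None
    buf: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if acc is not None:
                if acc in seqs:
                    logger.warning("duplicate accession %s: last entry wins", acc)
                seqs[acc] = "".join(buf)
            acc = line[1:].split()[0]
            buf = []
        else:
            buf.append(line.strip())
    if acc is not None:
        if acc in seqs:
            logger.warning("duplicate accession %s: last entry wins", acc)
        seqs[acc] = "".join(buf)
    return seqs


def tryptic_peptides(
    sequence: str, missed_cleavages: int = 0, min_len: int = 5, max_len: int = 50
) -> set[str]:
    """Fully tryptic peptides: cleave after K/R except before P."""
    sites = [0]
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P"):
            sites.append(i + 1)
    if sites[-1] != len(sequence):
        sites.append(len(sequence))
    peptides = set()
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(sites))):
            pep = sequence[sites[a]:sites[b]]
            if min_len <= len(pep) <= max_len:
                peptides.add(pep)
    return peptides


def digest_fasta(
    path: str | Path, missed_cleavages: int = 0, min_len: int = 5, max_len: int = 50
) -> dict[str, set[str]]:
    """Peptide -> protein accessions map from a tryptic FASTA digest."""
    protein_map: dict[str, set[str]] = {}
    for acc, seq in read_fasta(path).items():
        for pep in tryptic_peptides(seq, missed_cleavages, min_len, max_len):
            protein_map.setdefault(pep, set()).add(acc)
    return protein_map
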