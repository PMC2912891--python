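"""First-party Nexus reader/writer.

Supports DATA/CHARACTERS blocks (sequential or interleaved matrices), SETS
blocks with ``charset`` commands (ranges, steps, open-ended ranges), and the
``phyloga`` settings command block.  MATCHCHAR is not supported.  Taxon
labels containing whitespace must be single-quoted per Nexus convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .alignment import Alignment, AlignmentError, CharSet
from .settings import RunSettings

__all__ = ["read_nexus", "write_nexus", "NexusParseError", "NexusData"]


class NexusParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class NexusData:
    alignment: Alignment
    charsets: list[CharSet]
    settings: RunSettings


def _strip_comments(text: str) -> str:
    """Remove Nexus [comments], preserving newlines for line numbers."""
    out: list[str] = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth > 0:
                depth -= 1
            else:
                out.append(ch)
        elif depth == 0 or ch == "\n":
            out.append(ch)
    return "".join(out)


def _line_of(text: str, pos: int) -> int:
    return text.count("\n", 0, pos) + 1


_BLOCK_RE = re.compile(r"begin\s+(\w+)\s*;(.*?)\bend\s*;", re.IGNORECASE | re.DOTALL)


def read_nexus(source: str | Path) -> NexusData:
    """Parse a Nexus file (or literal text) into alignment, charsets, settings.

    A file without a ``phyloga`` block yields default :class:`RunSettings`.
    """
    try:
        is_file = Path(source).exists()
    except OSError:  # literal Nexus text, not a path
        is_file = False
    if is_file:
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().lower().startswith("#nexus"):
            raise NexusParseError(f"no such file: {source}")
    clean = _strip_comments(text)
    if not clean.lstrip().lower().startswith("#nexus"):
        raise NexusParseError("missing #NEXUS header", line=1)

    alignment: Alignment | None = None
    charsets: list[CharSet] = []
    settings = RunSettings()
    n_sites_hint: int | None = None

    for match in _BLOCK_RE.finditer(clean):
        block_name = match.group(1).lower()
        body = match.group(2)
        start_line = _line_of(clean, match.start())
        if block_name in ("data", "characters", "taxa"):
            if block_name == "taxa":
                continue
            alignment = _parse_data_block(body, start_line)
            n_sites_hint = alignment.n_sites
        elif block_name == "sets":
            charsets.extend(_parse_sets_block(body, start_line, n_sites_hint))
        elif block_name == "phyloga":
            settings = _parse_settings_block(body, start_line)
    if alignment is None:
        raise NexusParseError("no DATA or CHARACTERS block found")
    for cs in charsets:
        cs.validate_against(alignment)
    return NexusData(alignment, charsets, settings)


def _split_statements(body: str) -> list[str]:
    return [s.strip() for s in body.split(";") if s.strip()]


_TOKEN_RE = re.compile(r"'([^']*)'|(\S+)")


def _tokens(line: str) -> list[str]:
    return [a if a else b for a, b in _TOKEN_RE.findall(line)]


def _parse_data_block(body: str, start_line: int) -> Alignment:
    ntax = nchar = None
    interleave = False
    matrix_text = None
    for stmt in _split_statements(body):
        head = stmt.split(None, 1)[0].lower()
        if head == "dimensions":
            for key, value in re.findall(r"(\w+)\s*=\s*(\S+)", stmt):
                if key.lower() == "ntax":
                    ntax = int(value)
                elif key.lower() == "nchar":
                    nchar = int(value)
        elif head == "format":
            opts = dict((k.lower(), v) for k, v in re.findall(r"(\w+)\s*=?\s*([\w.?-]*)", stmt))
            interleave = "interleave" in opts and opts["interleave"].lower() not in ("no", "false")
            datatype = opts.get("datatype", "dna").lower()
            if datatype not in ("dna", "nucleotide", "rna", ""):
                raise NexusParseError(f"unsupported datatype {datatype!r}", start_line)
            if opts.get("matchchar"):
                raise NexusParseError("MATCHCHAR is not supported", start_line)
        elif head == "matrix":
            matrix_text = stmt.split(None, 1)[1] if len(stmt.split(None, 1)) > 1 else ""
    if matrix_text is None:
        raise NexusParseError("DATA block has no MATRIX command", start_line)

    taxa: list[str] = []
    seqs: dict[str, list[str]] = {}
    for raw_line in matrix_text.splitlines():
        line = raw_line.strip()
        if not line:
            continue
        toks = _tokens(line)
        name, chunks = toks[0], toks[1:]
        if not chunks:
            raise NexusParseError(f"matrix row for {name!r} has no sequence", start_line)
        seq = "".join(chunks)
        if name not in seqs:
            if not interleave and name in taxa:
                raise NexusParseError(f"duplicate taxon {name!r}", start_line)
            taxa.append(name)
            seqs[name] = []
        seqs[name].append(seq)
    sequences = {t: "".join(parts) for t, parts in seqs.items()}
    if len(set(taxa)) != len(taxa):
        raise NexusParseError("duplicate taxon label in matrix", start_line)
    try:
        alignment = Alignment(taxa, sequences)
    except AlignmentError as exc:
        raise NexusParseError(str(exc), start_line) from exc
    if ntax is not None and alignment.n_tax != ntax:
        raise NexusParseError(f"NTAX={ntax} but matrix has {alignment.n_tax} taxa", start_line)
    if nchar is not None and alignment.n_sites != nchar:
        raise NexusParseError(f"NCHAR={nchar} but matrix has {alignment.n_sites} sites", start_line)
    return alignment


def _parse_sets_block(body: str, start_line: int, n_sites: int | None) -> list[CharSet]:
    charsets = []
    for stmt in _split_statements(body):
        parts = stmt.split(None, 1)
        if parts[0].lower() != "charset":
            continue
        if "=" not in parts[1]:
            raise NexusParseError(f"malformed charset statement: {stmt!r}", start_line)
        name, spec = parts[1].split("=", 1)
        charsets.append(CharSet.from_spec(name.strip(), spec.strip(), n_sites))
    return charsets


def _parse_settings_block(body: str, start_line: int) -> RunSettings:
    statements: dict[str, str] = {}
    for stmt in _split_statements(body):
        if "=" not in stmt:
            raise NexusParseError(f"settings statement without '=': {stmt!r}", start_line)
        key, value = stmt.split("=", 1)
        statements[key.strip()] = value.strip()
    return RunSettings.from_statements(statements)


def _quote(label: str) -> str:
    return f"'{label}'" if re.search(r"\s", label) else label


def write_nexus(
    alignment: Alignment,
    charsets: list[CharSet] | None = None,
    settings: RunSettings | None = None,
    path: str | Path | None = None,
) -> str:
    """Serialize to Nexus; returns the text and optionally writes ``path``."""
    width = max(len(_quote(t)) for t in alignment.taxa) + 2
    lines = [
        "#NEXUS",
        "",
        "begin data;",
        f"    dimensions ntax={alignment.n_tax} nchar={alignment.n_sites};",
        "    format datatype=dna missing=? gap=-;",
        "    matrix",
    ]
    for taxon in alignment.taxa:
        lines.append(f"        {_quote(taxon):<{width}}{alignment.sequences[taxon]}")
    lines += ["    ;", "end;"]
    if charsets:
        lines += ["", "begin sets;"]
        for cs in charsets:
            lines.append(f"    charset {cs.name} = {_format_sites(cs.sites)};")
        lines.append("end;")
    if settings is not None:
        lines += ["", settings.to_block()]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _format_sites(sites: frozenset[int]) -> str:
    """Render a site set as compact Nexus ranges."""
    ordered = sorted(sites)
    parts: list[str] = []
    start = prev = ordered[0]
    for s in ordered[1:] + [None]:
        if s is not None and s == prev + 1:
            prev = s
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        if s is not None:
            start = prev = s
    return " ".join(parts)
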