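"""Corpus ingestion: PubMed XML, MEDLINE flat text and JSON-lines dialects.

A corpus is an ordered, PMID-unique collection of :class:`AbstractRecord`.
Only citations with a non-empty abstract are admitted to extraction (the
source query is restricted to articles that have an abstract); citations
without one are counted on the corpus rather than silently dropped.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Medline
from lxml import etree

__all__ = [
    "AbstractRecord",
    "Corpus",
    "CorpusError",
    "pubmed_query",
    "read_pubmed_xml",
    "read_medline_text",
    "read_jsonl",
    "write_jsonl",
    "write_medline_text",
]


class CorpusError(ValueError):
    """Raised for malformed corpus files or records."""


#: Verbatim PubMed boolean query used to assemble the epidemiological
#: criminology corpus (offender/prison terms crossed with the epidemiology
#: MeSH heading, every PubMed publication type, and randomisation /
#: natural-experiment / synthetic-control free text).  Typographic quotes
#: normalised to ASCII.
_PUBMED_QUERY = (
    "prison OR borstal OR jail OR jails OR gaol OR gaols OR penitentiary OR "
    "custody OR custodial OR (corrective AND (service or services)) OR "
    "((correctional or detention) AND (centre or centres OR center OR centers "
    "OR complex OR complexes or facility or facilities)) OR (closed AND "
    "(setting)) OR prisoner OR prisoners OR incarcerated OR criminals OR "
    "criminal OR felon OR felons OR remandee OR remandees OR delinquent OR "
    "delinquents OR detainee OR detainees OR convict OR convicts OR cellmate "
    "OR cellmates OR offenders OR offender OR ((young OR adolescent) AND "
    "(offender OR offenders)) OR ((delinquent OR incarcerated) AND youth) OR "
    "(juvenile AND (delinquents OR delinquent OR delinquency OR detainee OR "
    "detainees OR offender OR offenders)) OR ((young) AND (people) AND (in) "
    "AND (custody)) OR ((justice) AND (involved) AND (youth)) OR "
    "((incarcerated) AND (young) AND (people OR person OR persons)) OR "
    "((juvenile OR juveniles) AND (in) AND (custody)) AND english[lang] AND "
    '("epidemiology"[Subheading] OR "epidemiology"[MeSH Terms] OR '
    "epidemiology[Text Word] OR clinical study[publication type] OR case "
    "reports[publication type] OR clinical trial[publication type] OR "
    "clinical trial, phase i[publication type] OR clinical trial, phase "
    "ii[publication type] OR clinical trial, phase iii[publication type] OR "
    "clinical trial, phase iv[publication type] OR comparative "
    "study[publication type] OR controlled clinical trial[publication type] "
    "OR evaluation study[publication type] OR meta-analysis[publication "
    "type] OR multicenter study[publication type] OR observational "
    "study[publication type] OR pragmatic clinical trial[publication type] "
    "OR randomised controlled trial[publication type] OR review[publication "
    "type] OR systematic review[publication type] OR twin study[publication "
    "type] OR validation study[publication type] OR non randomised "
    "trial[text word] OR non randomised trial[text word] OR randomization "
    "experiment OR randomisation experiment OR natural experiment OR "
    "synthetic control)"
)


def pubmed_query() -> str:
    """Return the verbatim PubMed query the corpus is defined by."""
    return _PUBMED_QUERY


@dataclass
class AbstractRecord:
    """One PubMed citation reduced to the fields extraction needs."""

    pmid: str
    title: str = ""
    abstract_text: str = ""
    pub_year: int | None = None
    pub_types: list[str] = field(default_factory=list)
    language: str = "eng"

    def __post_init__(self) -> None:
        if not self.pmid:
            raise CorpusError("record with empty PMID")
        if self.pub_year is not None and not (1900 <= self.pub_year <= 9999):
            raise CorpusError(
                f"PMID {self.pmid}: pub_year {self.pub_year} is not a plausible 4-digit year"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "pmid": self.pmid,
                "title": self.title,
                "abstract_text": self.abstract_text,
                "pub_year": self.pub_year,
                "pub_types": self.pub_types,
                "language": self.language,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "AbstractRecord":
        d = json.loads(line)
        return cls(
            pmid=str(d["pmid"]),
            title=d.get("title", ""),
            abstract_text=d.get("abstract_text", ""),
            pub_year=d.get("pub_year"),
            pub_types=list(d.get("pub_types", [])),
            language=d.get("language", "eng"),
        )


@dataclass
class Corpus:
    """Ordered, PMID-unique collection of records plus ingest bookkeeping."""

    records: list[AbstractRecord] = field(default_factory=list)
    source_description: str = ""
    n_skipped_no_abstract: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise CorpusError(f"duplicate PMID {rec.pmid} in corpus")
            seen.add(rec.pmid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self.records)

    def __getitem__(self, pmid: str) -> AbstractRecord:
        for rec in self.records:
            if rec.pmid == pmid:
                return rec
        raise KeyError(pmid)


def _dedupe(records: Iterable[AbstractRecord], source: str) -> list[AbstractRecord]:
    out: list[AbstractRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.pmid in seen:
            warnings.warn(
                f"{source}: duplicate PMID {rec.pmid}; keeping first occurrence",
                stacklevel=3,
            )
            continue
        seen.add(rec.pmid)
        out.append(rec)
    return out


def _year_from_date(date_text: str | None) -> int | None:
    if not date_text:
        return None
    m = re.match(r"\s*(\d{4})", date_text)
    return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# PubMed XML (PubmedArticleSet dialect)
# ---------------------------------------------------------------------------

def _abstract_from_article(article: etree._Element) -> str:
    """Concatenate AbstractText sections, keeping structured labels."""
    parts: list[str] = []
    for node in article.findall(".//Abstract/AbstractText"):
        text = "".join(node.itertext()).strip()
        if not text:
            continue
        label = node.get("Label")
        parts.append(f"{label.strip().upper()}: {text}" if label else text)
    return " ".join(parts)


def read_pubmed_xml(path: str | Path) -> Corpus:
    """Read a PubmedArticleSet XML file into a :class:`Corpus`.

    Citations without an abstract are skipped and counted; a citation
    without a PMID is an error naming its 0-based index in the file.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"{path}: malformed XML: {exc}") from exc

    records: list[AbstractRecord] = []
    skipped = 0
    citations = tree.findall(".//MedlineCitation")
    for idx, citation in enumerate(citations):
        pmid_node = citation.find("PMID")
        if pmid_node is None or not (pmid_node.text or "").strip():
            raise CorpusError(f"{path}: citation {idx} lacks a PMID")
        pmid = pmid_node.text.strip()
        abstract = _abstract_from_article(citation)
        if not abstract:
            skipped += 1
            continue
        title_node = citation.find(".//ArticleTitle")
        title = "".join(title_node.itertext()).strip() if title_node is not None else ""
        year_node = citation.find(".//Article/Journal/JournalIssue/PubDate/Year")
        if year_node is not None and year_node.text:
            pub_year: int | None = int(year_node.text.strip())
        else:
            medline_date = citation.find(".//PubDate/MedlineDate")
            pub_year = _year_from_date(medline_date.text if medline_date is not None else None)
        pub_types = [
            ("".join(n.itertext())).strip()
            for n in citation.findall(".//PublicationTypeList/PublicationType")
        ]
        lang_node = citation.find(".//Language")
        language = lang_node.text.strip() if lang_node is not None and lang_node.text else "eng"
        records.append(
            AbstractRecord(
                pmid=pmid,
                title=title,
                abstract_text=abstract,
                pub_year=pub_year,
                pub_types=pub_types,
                language=language,
            )
        )
    return Corpus(
        records=_dedupe(records, str(path)),
        source_description=f"pubmed-xml:{path.name}",
        n_skipped_no_abstract=skipped,
    )


# ---------------------------------------------------------------------------
# MEDLINE flat text
# ---------------------------------------------------------------------------

def read_medline_text(path: str | Path) -> Corpus:
    """Read MEDLINE tagged flat text (PMID-/TI-/AB-/DP-/PT-/LA- fields)."""
    path = Path(path)
    records: list[AbstractRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as handle:
        for idx, rec in enumerate(Medline.parse(handle)):
            if not rec:
                continue
            pmid = (rec.get("PMID") or "").strip()
            if not pmid:
                raise CorpusError(f"{path}: record {idx} lacks a PMID field")
            abstract = (rec.get("AB") or "").strip()
            if not abstract:
                skipped += 1
                continue
            languages = rec.get("LA") or ["eng"]
            records.append(
                AbstractRecord(
                    pmid=pmid,
                    title=(rec.get("TI") or "").strip(),
                    abstract_text=abstract,
                    pub_year=_year_from_date(rec.get("DP")),
                    pub_types=list(rec.get("PT") or []),
                    language=languages[0],
                )
            )
    return Corpus(
        records=_dedupe(records, str(path)),
        source_description=f"medline:{path.name}",
        n_skipped_no_abstract=skipped,
    )


def write_medline_text(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back out as MEDLINE tagged flat text."""
    def tag(key: str, value: str) -> str:
        return f"{key.ljust(4)}- {value}"

    blocks: list[str] = []
    for rec in corpus:
        lines = [tag("PMID", rec.pmid)]
        if rec.pub_year is not None:
            lines.append(tag("DP", str(rec.pub_year)))
        if rec.title:
            lines.append(tag("TI", rec.title))
        lines.append(tag("AB", rec.abstract_text))
        for pt in rec.pub_types:
            lines.append(tag("PT", pt))
        lines.append(tag("LA", rec.language))
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON-lines
# ---------------------------------------------------------------------------

def read_jsonl(path: str | Path) -> Corpus:
    path = Path(path)
    records = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                records.append(AbstractRecord.from_json(line))
    return Corpus(records=_dedupe(records, str(path)), source_description=f"jsonl:{path.name}")


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for rec in corpus:
            handle.write(rec.to_json() + "\n")
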