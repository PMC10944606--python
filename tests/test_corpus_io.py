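"""Corpus ingestion: PubMed XML, MEDLINE flat text, JSONL, round trips."""

import pytest

from designminer import (
    AbstractRecord,
    Corpus,
    CorpusError,
    GeneratorConfig,
    generate,
    pubmed_query,
    read_jsonl,
    read_medline_text,
    read_pubmed_xml,
    write_jsonl,
    write_medline_text,
)
from designminer.synthetic import as_corpus

XML_HEADER = '<?xml version="1.0"?>\n<PubmedArticleSet>'
XML_FOOTER = "</PubmedArticleSet>"


def _citation(pmid, abstract_parts=(), title="T", year="2001"):
    parts = "".join(
        f'<AbstractText Label="{label}">{text}</AbstractText>' if label
        else f"<AbstractText>{text}</AbstractText>"
        for label, text in abstract_parts
    )
    abstract = f"<Abstract>{parts}</Abstract>" if abstract_parts else ""
    return (
        f"<PubmedArticle><MedlineCitation><PMID>{pmid}</PMID>"
        f"<Article><Journal><JournalIssue><PubDate><Year>{year}</Year></PubDate>"
        f"</JournalIssue></Journal><ArticleTitle>{title}</ArticleTitle>{abstract}"
        f"<Language>eng</Language></Article>"
        f"<PublicationTypeList><PublicationType>Journal Article</PublicationType>"
        f"</PublicationTypeList></MedlineCitation></PubmedArticle>"
    )


class TestPubmedXml:
    def test_records_without_abstract_are_counted_not_dropped(self, tmp_path):
        doc = XML_HEADER + _citation("1", [(None, "A study.")]) + _citation("2", [(None, "B study.")]) + _citation("3") + XML_FOOTER
        f = tmp_path / "c.xml"
        f.write_text(doc)
        corpus = read_pubmed_xml(f)
        assert len(corpus) == 2
        assert corpus.n_skipped_no_abstract == 1

    def test_structured_abstract_sections_joined_with_labels(self, tmp_path):
        doc = XML_HEADER + _citation(
            "1", [("BACKGROUND", "Bg."), ("METHODS", "We did."), ("RESULTS", "Found.")]
        ) + XML_FOOTER
        f = tmp_path / "c.xml"
        f.write_text(doc)
        corpus = read_pubmed_xml(f)
        assert corpus.records[0].abstract_text == "BACKGROUND: Bg. METHODS: We did. RESULTS: Found."

    def test_duplicate_pmid_deduplicated_to_first_with_warning(self, tmp_path):
        doc = (
            XML_HEADER
            + _citation("1", [(None, "First.")])
            + _citation("1", [(None, "Second.")])
            + XML_FOOTER
        )
        f = tmp_path / "c.xml"
        f.write_text(doc)
        with pytest.warns(UserWarning, match="duplicate PMID"):
            corpus = read_pubmed_xml(f)
        assert len(corpus) == 1
        assert corpus.records[0].abstract_text == "First."

    def test_malformed_xml_is_a_corpus_error(self, tmp_path):
        f = tmp_path / "bad.xml"
        f.write_text("<PubmedArticleSet><oops")
        with pytest.raises(CorpusError, match="malformed XML"):
            read_pubmed_xml(f)

    def test_missing_pmid_names_offending_citation(self, tmp_path):
        doc = (
            XML_HEADER
            + "<PubmedArticle><MedlineCitation><Article><Abstract>"
            "<AbstractText>X.</AbstractText></Abstract></Article>"
            "</MedlineCitation></PubmedArticle>" + XML_FOOTER
        )
        f = tmp_path / "c.xml"
        f.write_text(doc)
        with pytest.raises(CorpusError, match="citation 0 lacks a PMID"):
            read_pubmed_xml(f)


class TestMedline:
    def test_basic_fields_parsed(self, tmp_path):
        f = tmp_path / "m.txt"
        f.write_text(
            "PMID- 1\nTI  - T\nAB  - we conducted a cross-sectional study of X.\n"
            "DP  - 2001 Jan\n"
        )
        corpus = read_medline_text(f)
        assert len(corpus) == 1
        rec = corpus.records[0]
        assert rec.pub_year == 2001
        assert rec.abstract_text == "we conducted a cross-sectional study of X."

    def test_continuation_lines_joined_with_single_space(self, tmp_path):
        f = tmp_path / "m.txt"
        f.write_text("PMID- 1\nAB  - first part\n      second part\nDP  - 1999\n")
        corpus = read_medline_text(f)
        assert corpus.records[0].abstract_text == "first part second part"

    def test_empty_file_yields_empty_corpus(self, tmp_path):
        f = tmp_path / "m.txt"
        f.write_text("")
        assert len(read_medline_text(f)) == 0

    def test_medline_round_trip_preserves_records(self, tmp_path):
        corpus = as_corpus(generate(GeneratorConfig(n_abstracts=25, seed=3)))
        out = tmp_path / "m.txt"
        write_medline_text(corpus, out)
        back = read_medline_text(out)
        assert [(r.pmid, r.abstract_text, r.pub_year) for r in corpus] == [
            (r.pmid, r.abstract_text, r.pub_year) for r in back
        ]

    def test_jsonl_round_trip(self, tmp_path):
        corpus = as_corpus(generate(GeneratorConfig(n_abstracts=10, seed=4)))
        out = tmp_path / "c.jsonl"
        write_jsonl(corpus, out)
        back = read_jsonl(out)
        assert [r.to_json() for r in corpus] == [r.to_json() for r in back]


def test_xml_and_medline_dialects_yield_identical_records(tmp_path):
    """The same citation content in both dialects produces equal records."""
    xml = XML_HEADER + _citation("7", [(None, "We conducted a cohort study of inmates.")], title="A title", year="1987") + XML_FOOTER
    fx = tmp_path / "c.xml"
    fx.write_text(xml)
    fm = tmp_path / "m.txt"
    fm.write_text(
        "PMID- 7\nDP  - 1987\nTI  - A title\n"
        "AB  - We conducted a cohort study of inmates.\nPT  - Journal Article\nLA  - eng\n"
    )
    rx = read_pubmed_xml(fx).records[0]
    rm = read_medline_text(fm).records[0]
    assert (rx.pmid, rx.title, rx.abstract_text, rx.pub_year, rx.pub_types, rx.language) == (
        rm.pmid, rm.title, rm.abstract_text, rm.pub_year, rm.pub_types, rm.language
    )


def test_corpus_rejects_duplicate_pmids_and_bad_years():
    with pytest.raises(CorpusError, match="duplicate PMID"):
        Corpus(records=[AbstractRecord(pmid="1", abstract_text="x"),
                        AbstractRecord(pmid="1", abstract_text="y")])
    with pytest.raises(CorpusError, match="plausible 4-digit year"):
        AbstractRecord(pmid="1", abstract_text="x", pub_year=190)


class TestQuery:
    def test_query_contains_the_defining_clauses(self):
        q = pubmed_query()
        assert 'epidemiology"[MeSH Terms]' in q
        assert q.startswith("prison OR borstal OR jail")
        assert q.rstrip(")").endswith("synthetic control")
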