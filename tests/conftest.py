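"""Shared fixtures: sample eligibility sections in the three common registry
layouts, a small concept lexicon, and synthetic corpus recipes."""

import pytest

from trialminer.eligibility import ConceptLexicon
from trialminer.protocol_io import CorpusSpec

# Sample eligibility section: inclusion/exclusion bullet list (with a
# trailing non-bullet disclaimer sentence, as registry records often carry).
INC_EXC_SECTION = """\
Inclusion Criteria:
- Diabetes mellitus, Type 2
- 25 < BMI < 45 kg/m2
- 7,5% < HbA1c < 9%
- Treated with a basal insulin, and at least 1 g metformin daily, for more than 3 months
Exclusion Criteria:
- Type 1 diabetes mellitus
- Treatment with OADs only
- Treatment with thiazolidinediones
- Pregnancy
- Likelihood of requiring treatment during the study period with drugs not permitted by the clinical study protocol
The above information is not intended to contain all considerations relevant to a patient's potential participation in a clinical trial.
"""

# Sample eligibility section: bullet list grouped under aspect headers.
ASPECT_SECTION = """\
DISEASE CHARACTERISTICS:
- Histologically confirmed adenocarcinoma, including:
- Breast cancer (female), meeting the following criteria:
- Stage I-III disease
- Has undergone complete surgical removal of invasive cancer by mastectomy or lumpectomy
- Newly diagnosed disease
- Scheduled to receive chemotherapy
PATIENT CHARACTERISTICS:
- Life expectancy > 6 months
- Fluent in English
- Not living in a nursing home
- No severe dementia
"""

# Sample eligibility section: free-text paragraphs.
FREE_TEXT_SECTION = """\
Patients with COPD: irreversible air-flow limitation (postbronchodilator FEV1/FVC < 70% according to GOLD guidelines). Patients already receiving inhalative therapy can continue their medication. Patients showing a partial reversibility after bronchodilation (postbronchodilator FEV1 increase > 150 ml but < 200 ml) and complaining respiratory symptoms (e.g. dyspnea at exertion) will be treated preoperatively with a short-acting beta-agonist to achieve optimal perioperative conditions.
Patients have to be in clinical stable condition (no symptoms of respiratory tract infection for at least 2 weeks prior to the study).
Patients without COPD: postbronchodilator FEV1/FVC > 70%.
"""


@pytest.fixture
def inc_exc_text() -> str:
    return INC_EXC_SECTION


@pytest.fixture
def aspect_text() -> str:
    return ASPECT_SECTION


@pytest.fixture
def free_text() -> str:
    return FREE_TEXT_SECTION


@pytest.fixture
def lexicon() -> ConceptLexicon:
    return ConceptLexicon(
        {
            "diabetes mellitus": ("C0011849", "Diabetes Mellitus", True),
            "type 2": ("C0441730", "Type 2", False),
            "pregnancy": ("C0032961", "Pregnancy", True),
            "insulin": ("C0021641", "Insulin", True),
            "metformin": ("C0025598", "Metformin", False),
            "breast cancer": ("C0006142", "Breast Cancer", True),
            "cancer": ("C0006826", "Cancer", True),
            "chemotherapy": ("C0013216", "Chemotherapy", False),
            "asthma": ("C0004096", "Asthma", True),
            "inhaler": ("C0021461", "Inhaler", False),
            "depression": ("C0011570", "Depression", True),
            "ssri": ("C0360105", "SSRI", False),
        }
    )


def make_corpus_spec(
    n_clusters: int = 3,
    docs_per_cluster: int = 20,
    seed: int = 7,
    noise_rate: float = 0.0,
    vocab_size: int = 12,
) -> CorpusSpec:
    """Three-topic corpus recipe with pairwise-disjoint vocabularies and
    planted eligibility concepts."""
    stems = ("alpha", "beta", "gamma", "delta", "epsilon")[:n_clusters]
    concept_sets = (
        ("diabetes mellitus", "insulin"),
        ("asthma", "inhaler"),
        ("depression", "ssri"),
        ("breast cancer", "chemotherapy"),
        ("pregnancy", "metformin"),
    )[:n_clusters]
    return CorpusSpec(
        n_clusters=n_clusters,
        docs_per_cluster=docs_per_cluster,
        vocabulary_per_cluster=tuple(
            tuple(f"{stem}{i}" for i in range(vocab_size)) for stem in stems
        ),
        shared_vocabulary=tuple(f"shared{i}" for i in range(8)),
        concepts_per_cluster=concept_sets,
        seed=seed,
        noise_rate=noise_rate,
    )


@pytest.fixture
def corpus_spec() -> CorpusSpec:
    return make_corpus_spec()
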