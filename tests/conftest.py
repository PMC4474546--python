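import copy

import pytest

from rdmlkit import generate_document
from rdmlkit.model import Annotation, RdmlDocument, Sample
from rdmlkit.synth import SyntheticRunSpec, SyntheticTarget


@pytest.fixture(scope="session")
def doc12() -> RdmlDocument:
    return generate_document(SyntheticRunSpec(version="1.2", seed=1))


@pytest.fixture(scope="session")
def doc11() -> RdmlDocument:
    return generate_document(SyntheticRunSpec(version="1.1", seed=2))


@pytest.fixture(scope="session")
def doc10() -> RdmlDocument:
    return generate_document(SyntheticRunSpec(version="1.0", seed=3))


@pytest.fixture()
def clean12(doc12) -> RdmlDocument:
    """Mutable copy of the clean 1.2 fixture."""
    return copy.deepcopy(doc12)


@pytest.fixture(scope="session")
def noise_free_doc() -> RdmlDocument:
    return generate_document(SyntheticRunSpec(
        noiseSd=0.0, cqNoiseSd=0.0,
        targets=[SyntheticTarget(trueEfficiency=2.0)]))


# ---------------------------------------------------------------------------
# defect injection: each operator breaks exactly one validation rule in a
# clean document and returns (expected issue code, path fragment)

def _dangling_reference(doc):
    doc.experiments[0].runs[0].reactions[0].sampleRef = "s_missing"
    return "dangling-reference", "react[1]"


def _duplicate_id(doc):
    doc.samples.append(Sample(id=doc.samples[0].id))
    return "duplicate-id", f"sample[{doc.samples[0].id}]"


def _dye_unregistered(doc):
    doc.targets[0].dyeRef = None
    return "dye-unregistered", f"target[{doc.targets[0].id}]"


def _position_out_of_bounds(doc):
    doc.experiments[0].runs[0].reactions[0].position = 10_000
    return "position-out-of-bounds", "react[10000]"


def _non_monotone_cycles(doc):
    data = doc.experiments[0].runs[0].reactions[0].data[0]
    data.amplificationPoints[3], data.amplificationPoints[2] = (
        data.amplificationPoints[2], data.amplificationPoints[3])
    return "non-monotone-cycles", "react[1]"


def _element_wrong_version(doc):
    # an annotation outside version 1.2
    doc.version = "1.1"
    doc.samples[0].annotations.append(Annotation("group", "a"))
    return "element-wrong-version", f"sample[{doc.samples[0].id}]"


DEFECT_OPERATORS = {
    "dangling-reference": _dangling_reference,
    "duplicate-id": _duplicate_id,
    "dye-unregistered": _dye_unregistered,
    "position-out-of-bounds": _position_out_of_bounds,
    "non-monotone-cycles": _non_monotone_cycles,
    "element-wrong-version": _element_wrong_version,
}
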