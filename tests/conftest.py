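import pytest

from smearseq.variants import CallSet, VariantCall


def make_call(pos=100, ref="A", alt="T", vaf=0.3, depth=100, **kw):
    kw.setdefault("caller_class", "somatic")
    return VariantCall(chrom="chr1", pos=pos, ref=ref, alt=alt, vaf=vaf, depth=depth, **kw)


def make_callset(positions, tissue="smear", sample_id="S1", caller_class="somatic", **kw):
    calls = [make_call(pos=p, caller_class=caller_class, **kw) for p in positions]
    return CallSet(sample_id, tissue, caller_class, calls)


@pytest.fixture
def toy_pair():
    """smear {100,200,300}, bmc {200,300,400}: 2 shared, 1 unique each."""
    smear = make_callset([100, 200, 300], tissue="smear")
    bmc = make_callset([200, 300, 400], tissue="bmc", sample_id="B1")
    return smear, bmc
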