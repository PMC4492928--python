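import pytest

from forgetfit import load_table2, load_table3


@pytest.fixture(scope="session")
def table3():
    """The four canonical savings curves on the uniform fitting grid."""
    return load_table3()


@pytest.fixture(scope="session")
def ebbinghaus_curve(table3):
    return table3["Ebbinghaus"]


@pytest.fixture(scope="session")
def dros_curve(table3):
    return table3["Dros"]


@pytest.fixture(scope="session")
def table2_records():
    return load_table2()
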