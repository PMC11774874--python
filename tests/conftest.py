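import numpy as np
import pytest

import rhizonet as rz

#: 10-tip ultrametric tree (depth 1.5) used as a cross-validation fixture;
#: expected values for it were frozen from independent reference software
ORACLE_NEWICK = ("((((t1:0.3,t2:0.3):0.4,(t3:0.5,t4:0.5):0.2):0.3,"
                 "((t5:0.6,t6:0.6):0.2,t7:0.8):0.2):0.5,"
                 "(t8:0.9,(t9:0.4,t10:0.4):0.5):0.6);")

ORACLE_X = np.array([1.2, 1.5, 0.3, 0.7, -0.4, -0.1, 2.2, 0.9, -1.3, -0.8])
ORACLE_Y = np.array([2.0, 2.6, 1.1, 1.4, 0.2, 0.5, 3.9, 2.1, -1.9, -1.0])


@pytest.fixture(scope="session")
def oracle_tree():
    return rz.parse_newick(ORACLE_NEWICK)


@pytest.fixture(scope="session")
def oracle_vcv(oracle_tree):
    # matrix ordered t1..t10 to match the frozen reference values
    return oracle_tree.vcv().subset([f"t{i}" for i in range(1, 11)])


@pytest.fixture(scope="session")
def oracle_xy():
    return ORACLE_X.copy(), ORACLE_Y.copy()


@pytest.fixture(scope="session")
def table1():
    return rz.table1_fixture()


@pytest.fixture(scope="session")
def table3():
    return rz.table3_fixture()


@pytest.fixture()
def star_vcv():
    """5-tip star tree: C = t * I with t = 2."""
    tree = rz.parse_newick("(A:2,B:2,C:2,D:2,E:2);")
    return tree.vcv()
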