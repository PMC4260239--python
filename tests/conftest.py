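"""Shared fixtures: worked Michaelis-Menten instantiations and SBML documents.

Two parameter regimes of the enzymatic mechanism recur throughout the suite:

* ``regime A`` (dissociation faster than catalysis, order(k_-1) < order(k2)):
  every equilibration balances both variables; two branches.
* ``regime B`` (catalysis faster, order(k2) < order(k_-1)): four branches,
  two of which equilibrate only one variable.
"""

import pytest

from tropicalize.fixtures import (FixtureSpec, michaelis_menten_full,
                                  michaelis_menten_reduced,
                                  michaelis_menten_unreduced)
from tropicalize.polynomial_system import build_odes


@pytest.fixture
def spec_regime_a() -> FixtureSpec:
    return FixtureSpec(name="mm-a",
                       parameter_orders={"k1": 0, "k_1": 0, "k2": 1, "e": 1})


@pytest.fixture
def spec_regime_b() -> FixtureSpec:
    return FixtureSpec(name="mm-b",
                       parameter_orders={"k1": 0, "k_1": 2, "k2": 0, "e": 1})


@pytest.fixture
def mm_network(spec_regime_a):
    return michaelis_menten_full(spec_regime_a)


@pytest.fixture
def mm_system(mm_network, spec_regime_a):
    return build_odes(mm_network, spec_regime_a.epsilon)


@pytest.fixture
def reduced_a(spec_regime_a):
    return michaelis_menten_reduced(spec_regime_a)


@pytest.fixture
def reduced_b(spec_regime_b):
    return michaelis_menten_reduced(spec_regime_b)


MM_TEXT = """\
# Michaelis-Menten mechanism
init: S = 1.0
init: E = 0.1
S + E -> ES ; k=1.0
ES -> S + E ; k=1.0
ES -> P + E ; k=0.1
"""


SBML_HEADER = ('<?xml version="1.0" encoding="UTF-8"?>\n'
               '<sbml xmlns="http://www.sbml.org/sbml/level2/version4" '
               'level="2" version="4">')

MM_SBML = f"""{SBML_HEADER}
  <model id="mm">
    <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
    <listOfSpecies>
      <species id="S" compartment="cell" initialConcentration="1.0"/>
      <species id="ES" compartment="cell" initialConcentration="0.0"/>
      <species id="E" compartment="cell" initialConcentration="0.1"/>
      <species id="P" compartment="cell" initialConcentration="0.0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k1" value="1.0"/>
      <parameter id="km1" value="1.0"/>
      <parameter id="k2" value="0.1"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="bind" reversible="true">
        <listOfReactants>
          <speciesReference species="S"/>
          <speciesReference species="E"/>
        </listOfReactants>
        <listOfProducts><speciesReference species="ES"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><minus/>
              <apply><times/><ci>k1</ci><ci>S</ci><ci>E</ci></apply>
              <apply><times/><ci>km1</ci><ci>ES</ci></apply>
            </apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="cat">
        <listOfReactants><speciesReference species="ES"/></listOfReactants>
        <listOfProducts>
          <speciesReference species="P"/>
          <speciesReference species="E"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>k2</ci><ci>ES</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

RATIONAL_SBML = f"""{SBML_HEADER}
  <model id="ratl">
    <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
    <listOfSpecies>
      <species id="S" compartment="cell" initialConcentration="1.0"/>
      <species id="P" compartment="cell" initialConcentration="0.0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="Vm" value="1.0"/><parameter id="Km" value="0.5"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="mmlaw">
        <listOfReactants><speciesReference species="S"/></listOfReactants>
        <listOfProducts><speciesReference species="P"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><divide/>
              <apply><times/><ci>Vm</ci><ci>S</ci></apply>
              <apply><plus/><ci>Km</ci><ci>S</ci></apply>
            </apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

EMPTY_SBML = f"""{SBML_HEADER}
  <model id="empty">
    <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialConcentration="1.0"/>
    </listOfSpecies>
  </model>
</sbml>
"""

BOUNDARY_SBML = f"""{SBML_HEADER}
  <model id="boundary">
    <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
    <listOfSpecies>
      <species id="X" compartment="cell" initialConcentration="2.0"
               boundaryCondition="true"/>
      <species id="Y" compartment="cell" initialConcentration="0.5"/>
    </listOfSpecies>
    <listOfParameters><parameter id="k" value="3.0"/></listOfParameters>
    <listOfReactions>
      <reaction id="conv">
        <listOfReactants><speciesReference species="X"/></listOfReactants>
        <listOfProducts><speciesReference species="Y"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>k</ci><ci>X</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture
def sbml_dir(tmp_path):
    (tmp_path / "mm.xml").write_text(MM_SBML)
    (tmp_path / "rational.xml").write_text(RATIONAL_SBML)
    (tmp_path / "empty.xml").write_text(EMPTY_SBML)
    (tmp_path / "boundary.xml").write_text(BOUNDARY_SBML)
    return tmp_path
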