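<Lems>
    <!-- Shared dimensions and units for the fixture catalog.
         Dimensions are 7-tuples over (m, l, t, i, k, n, j); units carry a
         power of ten relative to SI.  Fixtures set parameters in
         millisecond/millivolt-friendly units to exercise conversion, while
         traces are SI on output. -->

    <Dimension name="voltage" m="1" l="2" t="-3" i="-1"/>
    <Dimension name="time" t="1"/>
    <Dimension name="per_time" t="-1"/>
    <Dimension name="conductance" m="-1" l="-2" t="3" i="2"/>
    <Dimension name="capacitance" m="-1" l="-2" t="4" i="2"/>
    <Dimension name="current" i="1"/>
    <Dimension name="concentration" l="-3" n="1"/>

    <Unit symbol="V" dimension="voltage" power="0"/>
    <Unit symbol="mV" dimension="voltage" power="-3"/>
    <Unit symbol="s" dimension="time" power="0"/>
    <Unit symbol="ms" dimension="time" power="-3"/>
    <Unit symbol="per_s" dimension="per_time" power="0"/>
    <Unit symbol="per_ms" dimension="per_time" power="3"/>
    <Unit symbol="S" dimension="conductance" power="0"/>
    <Unit symbol="mS" dimension="conductance" power="-3"/>
    <Unit symbol="uS" dimension="conductance" power="-6"/>
    <Unit symbol="nS" dimension="conductance" power="-9"/>
    <Unit symbol="F" dimension="capacitance" power="0"/>
    <Unit symbol="uF" dimension="capacitance" power="-6"/>
    <Unit symbol="nF" dimension="capacitance" power="-9"/>
    <Unit symbol="pF" dimension="capacitance" power="-12"/>
    <Unit symbol="A" dimension="current" power="0"/>
    <Unit symbol="mA" dimension="current" power="-3"/>
    <Unit symbol="uA" dimension="current" power="-6"/>
    <Unit symbol="nA" dimension="current" power="-9"/>
    <Unit symbol="pA" dimension="current" power="-12"/>
    <!-- 1 mM = 1 mmol/L = 1 mol/m^3, which is the SI unit -->
    <Unit symbol="mM" dimension="concentration" power="0"/>
    <Unit symbol="M" dimension="concentration" power="3"/>
</Lems>
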