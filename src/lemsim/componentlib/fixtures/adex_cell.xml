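<Lems>
    <!-- Adaptive exponential integrate-and-fire cell, reference regular-
         spiking parameterization, driven by a 0.8 nA step from 50 ms. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>
    <Include file="adextypes.xml"/>

    <adExCell id="adex" C="281 pF" gL="30 nS" EL="-70.6 mV" VT="-50.4 mV"
              delT="2 mV" Vr="-70.6 mV" a="4 nS" b="80.5 pA" tauw="144 ms"
              refract="2 ms" threshold="-40 mV">
        <input type="pulseGenerator" delay="50 ms" duration="200 ms"
               amplitude="0.8 nA"/>
    </adExCell>

    <Simulation id="sim" length="300 ms" step="0.025 ms" target="adex">
        <Display id="d0">
            <Line quantity="adex/v"/>
            <Line quantity="adex/w"/>
        </Display>
        <OutputFile id="of0" fileName="adex_cell.tsv">
            <OutputColumn quantity="adex/v"/>
            <OutputColumn quantity="adex/w"/>
            <OutputColumn quantity="adex/input/i"/>
        </OutputFile>
    </Simulation>

    <Target component="sim"/>
</Lems>
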