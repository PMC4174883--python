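<Lems>
    <!-- Classic squid-axon sodium + potassium + leak conductances (1952
         parameterization, 1 cm^2 membrane) on a point cell, with a
         suprathreshold current step at 50 ms. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>
    <Include file="hhtypes.xml"/>

    <hhCell id="hhcell" C="1 uF" v0="-65 mV" threshold="0 mV">
        <ionChannelHH id="naChan" conductance="120 mS" erev="50 mV">
            <gateHHrates id="m" instances="3">
                <forwardRate type="expLinearRate" rate="1 per_ms"
                             midpoint="-40 mV" scale="10 mV"/>
                <reverseRate type="expOneRate" rate="4 per_ms"
                             midpoint="-65 mV" scale="-18 mV"/>
            </gateHHrates>
            <gateHHrates id="h" instances="1">
                <forwardRate type="expOneRate" rate="0.07 per_ms"
                             midpoint="-65 mV" scale="-20 mV"/>
                <reverseRate type="sigmoidRate" rate="1 per_ms"
                             midpoint="-35 mV" scale="10 mV"/>
            </gateHHrates>
        </ionChannelHH>
        <ionChannelHH id="kChan" conductance="36 mS" erev="-77 mV">
            <gateHHrates id="n" instances="4">
                <forwardRate type="expLinearRate" rate="0.1 per_ms"
                             midpoint="-55 mV" scale="10 mV"/>
                <reverseRate type="expOneRate" rate="0.125 per_ms"
                             midpoint="-65 mV" scale="-80 mV"/>
            </gateHHrates>
        </ionChannelHH>
        <passiveChannel id="leak" conductance="0.3 mS" erev="-54.387 mV"/>
        <input type="pulseGenerator" delay="50 ms" duration="50 ms"
               amplitude="10 uA"/>
    </hhCell>

    <Simulation id="sim" length="120 ms" step="0.025 ms" target="hhcell">
        <Display id="d0">
            <Line quantity="hhcell/v"/>
        </Display>
        <OutputFile id="of0" fileName="hh_cell.tsv">
            <OutputColumn quantity="hhcell/v"/>
            <OutputColumn quantity="hhcell/naChan/m/q"/>
            <OutputColumn quantity="hhcell/naChan/h/q"/>
            <OutputColumn quantity="hhcell/kChan/n/q"/>
            <OutputColumn quantity="hhcell/input/i"/>
        </OutputFile>
    </Simulation>

    <Target component="sim"/>
</Lems>
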