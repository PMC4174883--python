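<Lems>
    <!-- Adaptive exponential integrate-and-fire cell: membrane potential v
         and adaptation current w, with two regimes.  The integrating
         regime carries the exponential spike-initiation term and emits a
         spike event on threshold crossing; the refractory regime freezes v
         after applying the reset (OnEntry) and is left once the refractory
         period since the last spike has elapsed.  Synapses attach
         dynamically, one instance per incoming network connection. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>

    <ComponentType name="adExCell" extends="baseCellMembPot">
        <Parameter name="C" dimension="capacitance"/>
        <Parameter name="gL" dimension="conductance"/>
        <Parameter name="EL" dimension="voltage"/>
        <Parameter name="VT" dimension="voltage"/>
        <Parameter name="delT" dimension="voltage"/>
        <Parameter name="Vr" dimension="voltage"/>
        <Parameter name="a" dimension="conductance"/>
        <Parameter name="b" dimension="current"/>
        <Parameter name="tauw" dimension="time"/>
        <Parameter name="refract" dimension="time"/>
        <Parameter name="threshold" dimension="voltage"/>
        <Child name="input" type="basePointCurrent"/>
        <Attachments name="synapses" type="baseSynapse"/>
        <Exposure name="w" dimension="current"/>
        <Dynamics>
            <StateVariable name="v" dimension="voltage" exposure="v"/>
            <StateVariable name="w" dimension="current" exposure="w"/>
            <StateVariable name="lastSpike" dimension="time"/>
            <DerivedVariable name="iInput" dimension="current" select="input/i"/>
            <DerivedVariable name="iSyn" dimension="current"
                             select="synapses[*]/i" reduce="add"/>
            <OnStart>
                <StateAssignment variable="v" value="EL"/>
            </OnStart>
            <Regime name="integrating" initial="true">
                <TimeDerivative variable="v"
                    value="(gL * (EL - v) + gL * delT * exp((v - VT) / delT) - w + iInput + iSyn) / C"/>
                <TimeDerivative variable="w" value="(a * (v - EL) - w) / tauw"/>
                <OnCondition test="v .gt. threshold">
                    <EventOut port="spike"/>
                    <Transition regime="refractory"/>
                </OnCondition>
            </Regime>
            <Regime name="refractory">
                <TimeDerivative variable="w" value="(a * (v - EL) - w) / tauw"/>
                <OnEntry>
                    <StateAssignment variable="lastSpike" value="t"/>
                    <StateAssignment variable="v" value="Vr"/>
                    <StateAssignment variable="w" value="w + b"/>
                </OnEntry>
                <OnCondition test="t .geq. lastSpike + refract">
                    <Transition regime="integrating"/>
                </OnCondition>
            </Regime>
        </Dynamics>
    </ComponentType>
</Lems>
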