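<Lems>
    <!-- Hodgkin-Huxley style conductance types.  A channel owns zero or
         more two-state gates; each gate owns named forward/reverse rate
         children extending baseVoltageDepRate in one of the three standard
         functional forms (exponential, sigmoid, exponential-linear) of
         x = (v - midpoint)/scale, scaled by a constant rate factor. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>

    <ComponentType name="baseIonChannel">
        <Parameter name="conductance" dimension="conductance"/>
        <Parameter name="erev" dimension="voltage"/>
        <Requirement name="v" dimension="voltage"/>
        <Exposure name="g" dimension="conductance"/>
        <Exposure name="i" dimension="current"/>
    </ComponentType>

    <!-- Ohmic leak: fully open at all potentials. -->
    <ComponentType name="passiveChannel" extends="baseIonChannel">
        <Dynamics>
            <DerivedVariable name="g" dimension="conductance" exposure="g"
                             value="conductance"/>
            <DerivedVariable name="i" dimension="current" exposure="i"
                             value="g * (erev - v)"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="baseVoltageDepRate">
        <Requirement name="v" dimension="voltage"/>
        <Exposure name="r" dimension="per_time"/>
    </ComponentType>

    <ComponentType name="baseHHRate" extends="baseVoltageDepRate">
        <Parameter name="rate" dimension="per_time"/>
        <Parameter name="midpoint" dimension="voltage"/>
        <Parameter name="scale" dimension="voltage"/>
        <Dynamics>
            <DerivedVariable name="x" dimension="none"
                             value="(v - midpoint) / scale"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="expOneRate" extends="baseHHRate">
        <Dynamics>
            <DerivedVariable name="r" dimension="per_time" exposure="r"
                             value="rate * exp(x)"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="sigmoidRate" extends="baseHHRate">
        <Dynamics>
            <DerivedVariable name="r" dimension="per_time" exposure="r"
                             value="rate / (1 + exp(0 - x))"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="expLinearRate" extends="baseHHRate">
        <Dynamics>
            <DerivedVariable name="r" dimension="per_time" exposure="r"
                             value="rate * (x / (1 - exp(0 - x)))"/>
        </Dynamics>
    </ComponentType>

    <!-- One gating particle: q relaxes by dq/dt = alpha(1-q) - beta q and
         contributes fcond = q^instances to the channel open fraction.
         q starts at its steady state for the initial potential. -->
    <ComponentType name="gateHHrates">
        <Parameter name="instances" dimension="none"/>
        <Child name="forwardRate" type="baseVoltageDepRate"/>
        <Child name="reverseRate" type="baseVoltageDepRate"/>
        <Exposure name="q" dimension="none"/>
        <Exposure name="fcond" dimension="none"/>
        <Dynamics>
            <StateVariable name="q" dimension="none" exposure="q"/>
            <DerivedVariable name="alpha" dimension="per_time" select="forwardRate/r"/>
            <DerivedVariable name="beta" dimension="per_time" select="reverseRate/r"/>
            <DerivedVariable name="fcond" dimension="none" exposure="fcond"
                             value="q^instances"/>
            <TimeDerivative variable="q" value="alpha * (1 - q) - beta * q"/>
            <OnStart>
                <StateAssignment variable="q" value="alpha / (alpha + beta)"/>
            </OnStart>
        </Dynamics>
    </ComponentType>

    <ComponentType name="ionChannelHH" extends="baseIonChannel">
        <Children name="gates" type="gateHHrates"/>
        <Dynamics>
            <DerivedVariable name="fopen" dimension="none"
                             select="gates[*]/fcond" reduce="multiply"/>
            <DerivedVariable name="g" dimension="conductance" exposure="g"
                             value="conductance * fopen"/>
            <DerivedVariable name="i" dimension="current" exposure="i"
                             value="g * (erev - v)"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="baseCellMembPotCap" extends="baseCellMembPot">
        <Parameter name="C" dimension="capacitance"/>
    </ComponentType>

    <!-- Point cell: membrane capacitance fed by its channel currents and an
         input current; emits a spike event on upward threshold crossing. -->
    <ComponentType name="hhCell" extends="baseCellMembPotCap">
        <Parameter name="v0" dimension="voltage"/>
        <Parameter name="threshold" dimension="voltage"/>
        <Children name="channels" type="baseIonChannel"/>
        <Child name="input" type="basePointCurrent"/>
        <Exposure name="iChannels" dimension="current"/>
        <Dynamics>
            <StateVariable name="v" dimension="voltage" exposure="v"/>
            <DerivedVariable name="iChannels" dimension="current" exposure="iChannels"
                             select="channels[*]/i" reduce="add"/>
            <DerivedVariable name="iInput" dimension="current" select="input/i"/>
            <TimeDerivative variable="v" value="(iChannels + iInput) / C"/>
            <OnStart>
                <StateAssignment variable="v" value="v0"/>
            </OnStart>
            <OnCondition test="v .gt. threshold">
                <EventOut port="spike"/>
            </OnCondition>
        </Dynamics>
    </ComponentType>
</Lems>
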